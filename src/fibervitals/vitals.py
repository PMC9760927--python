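"""Per-minute respiratory-rate and heart-rate extraction from phase spectra.

The respiratory rate (RR) is the frequency of the global magnitude maximum
in the band above 0.5 Hz and capped at 2.5 Hz — breathing dominates the
spectrum, so the band maximum is the breathing fundamental. The heart rate
(HR) is searched among the five largest local maxima above 1.5 Hz (or above
RR + 0.25 Hz when the RR frequency is at or above 1.5 Hz); of these, the
lowest-frequency candidate exhibiting at least one additional harmonic
component is taken as the HR. Minutes distorted by motion are analyzed on a
clean 30 s sub-window when one exists, otherwise marked invalid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demod import demodulate_record
from .errors import InsufficientLengthError
from .spectral import Frame, SpectrumFrame, compute_spectrum, find_local_maxima, frame_signal
from .synth import CouplerRecord, PhaseSeries

__all__ = ["BandConfig", "VitalsEstimate", "estimate_rr", "has_harmonic",
           "estimate_hr", "detect_distortion", "bad_second_mask", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandConfig:
    """Frequency bands and thresholds of the RR/HR extraction rules.

    rr band (rr_lo_hz, rr_hi_hz] brackets breathing; the HR search starts at
    hr_start_hz, or at the RR frequency plus hr_offset_hz when RR reaches
    the start, and extends to hr_hi_hz (5.5 Hz = 330 beats/min, the
    physiological ceiling for the neonate-sized subjects the sensor
    targets). Candidate maxima below hr_min_rel_amp times the largest
    in-band magnitude are treated as noise-floor bins and never enter the
    five-candidate list. A candidate HR peak must show a local maximum within
    harmonic_tol_hz of twice its frequency, between harmonic_min_rel_amp and
    harmonic_max_rel_amp times its own magnitude; the upper cap rejects
    impostor candidates (typically a breathing harmonic) whose claimed
    "harmonic" is the stronger cardiac fundamental sitting near twice their
    frequency — a genuine fundamental's harmonic does not exceed it.
    harmonic_tol_hz defaults to 0.05 Hz — three
    bins at the 1/60 Hz resolution, enough for leakage and merged-peak
    shifts while rejecting accidental near-coincidences of breathing and
    cardiac harmonics. rr_floor_factor sets the noise-floor validity rule:
    the RR band maximum must exceed this multiple of the median in-band
    magnitude.
    """

    rr_lo_hz: float = 0.5
    rr_hi_hz: float = 2.5
    hr_start_hz: float = 1.5
    hr_offset_hz: float = 0.25
    hr_hi_hz: float = 5.5
    n_maxima: int = 5
    harmonic_tol_hz: float = 0.05
    harmonic_min_rel_amp: float = 0.05
    harmonic_max_rel_amp: float = 1.0
    rr_floor_factor: float = 3.0
    hr_min_rel_amp: float = 0.05
    distortion_threshold_k: float = 8.0

    def __post_init__(self):
        if not (self.rr_lo_hz < self.rr_hi_hz):
            raise ValueError("rr_lo_hz must be below rr_hi_hz")
        if self.hr_start_hz < self.rr_lo_hz:
            raise ValueError("hr_start_hz must be at or above rr_lo_hz")
        if self.n_maxima < 1:
            raise ValueError("n_maxima must be at least 1")


@dataclass(frozen=True)
class VitalsEstimate:
    """One minute's RR/HR estimates with validity flags."""

    minute_index: int
    rr_bpm: float | None
    hr_bpm: float | None
    rr_freq_hz: float | None
    hr_freq_hz: float | None
    valid_rr: bool
    valid_hr: bool
    distorted: bool


def estimate_rr(spec: SpectrumFrame, cfg: BandConfig = BandConfig()
                ) -> tuple[int, float] | None:
    """RR from the global magnitude maximum in (rr_lo, rr_hi] Hz.

    Returns (rr_bpm, rr_freq_hz), or None when the band is empty or its
    maximum does not clear the noise floor (rr_floor_factor x the median
    in-band magnitude).
    """
    eps = 1e-12
    band = (spec.freqs > cfg.rr_lo_hz) & (spec.freqs <= cfg.rr_hi_hz + eps)
    if spec.mags.size == 0 or not band.any():
        return None
    mags = spec.mags[band]
    freqs = spec.freqs[band]
    i = int(np.argmax(mags))
    floor = np.median(mags)
    if floor > 0 and mags[i] <= cfg.rr_floor_factor * floor:
        return None
    if mags[i] <= 0:
        return None
    return int(round(freqs[i] * 60.0)), float(freqs[i])


def has_harmonic(spec: SpectrumFrame, f0: float, cfg: BandConfig = BandConfig()) -> bool:
    """True iff a local maximum lies within harmonic_tol_hz of 2*f0 with
    magnitude between harmonic_min_rel_amp and harmonic_max_rel_amp times
    the magnitude at f0 (a harmonic stronger than its fundamental marks the
    candidate as itself a harmonic of a lower rate, not a fundamental)."""
    f2 = 2.0 * f0
    nyquist = spec.freqs[-1]
    if f2 > nyquist:
        return False
    mag0 = spec.mags[int(np.argmin(np.abs(spec.freqs - f0)))]
    lo = max(f2 - 2 * cfg.harmonic_tol_hz, 0.0)
    hi = min(f2 + 2 * cfg.harmonic_tol_hz, nyquist)
    if lo >= hi:
        return False
    for pk in find_local_maxima(spec, lo, hi):
        if abs(pk.freq_hz - f2) <= cfg.harmonic_tol_hz + 1e-9 \
                and cfg.harmonic_min_rel_amp * mag0 <= pk.mag <= cfg.harmonic_max_rel_amp * mag0:
            return True
    return False


def estimate_hr(spec: SpectrumFrame, rr_freq_hz: float | None,
                cfg: BandConfig = BandConfig()) -> tuple[int, float] | None:
    """HR by the five-maxima rule.

    The search band starts at hr_start_hz, or at rr_freq + hr_offset_hz when
    the RR frequency is at or above hr_start_hz, and ends at hr_hi_hz. Among
    the n_maxima largest local maxima, the lowest-frequency one with a
    harmonic is the HR. Returns (hr_bpm, hr_freq_hz) or None.
    """
    if rr_freq_hz is not None and rr_freq_hz >= cfg.hr_start_hz:
        f_start = rr_freq_hz + cfg.hr_offset_hz
    else:
        f_start = cfg.hr_start_hz
    peaks = find_local_maxima(spec, f_start, cfg.hr_hi_hz)
    if not peaks:
        return None
    floor = cfg.hr_min_rel_amp * max(p.mag for p in peaks)
    peaks = [p for p in peaks if p.mag >= floor][:cfg.n_maxima]
    qualified = [p for p in peaks if has_harmonic(spec, p.freq_hz, cfg)]
    if not qualified:
        return None
    best = min(qualified, key=lambda p: p.freq_hz)
    return int(round(best.freq_hz * 60.0)), float(best.freq_hz)


def _second_rms(phase: PhaseSeries) -> np.ndarray:
    """RMS of the first difference over non-overlapping 1 s windows."""
    d = np.diff(phase.values)
    n_sec = int(phase.duration_s)
    spw = int(round(phase.fs))
    rms = np.empty(n_sec)
    for s in range(n_sec):
        w = d[s * spw:min((s + 1) * spw, d.size)]
        rms[s] = np.sqrt(np.mean(w ** 2)) if w.size else 0.0
    return rms


def bad_second_mask(phase: PhaseSeries, threshold_k: float = 8.0) -> np.ndarray:
    """Per-second boolean mask: True where the 1 s first-difference RMS
    exceeds threshold_k times the record's median 1 s RMS."""
    rms = _second_rms(phase)
    med = np.median(rms)
    if not math.isfinite(med) or med == 0:
        return np.zeros_like(rms, dtype=bool)
    return rms > threshold_k * med


def detect_distortion(phase: PhaseSeries, minute_index: int,
                      threshold_k: float = 8.0) -> bool:
    """True iff any 1 s sub-interval of the minute has a first-difference RMS
    above threshold_k times the record's median 1 s RMS."""
    if math.isinf(threshold_k):
        return False
    bad = bad_second_mask(phase, threshold_k)
    lo, hi = minute_index * 60, (minute_index + 1) * 60
    if lo >= bad.size:
        raise IndexError(f"minute {minute_index} beyond record")
    return bool(bad[lo:hi].any())


def run_pipeline(record: CouplerRecord, cfg: BandConfig = BandConfig(),
                 equalization: str = "minmax") -> pd.DataFrame:
    """Full signal chain: equalize, demodulate, unwrap, detect distortion,
    frame, transform, extract RR and HR per minute.

    Returns a DataFrame with columns minute, rr_bpm, hr_bpm, rr_freq_hz,
    hr_freq_hz, valid_rr, valid_hr, distorted. Minutes without a clean 30 s
    sub-window are kept as rows but marked invalid.
    """
    if record.n / record.fs < 60:
        raise InsufficientLengthError(
            f"record of {record.n / record.fs:.1f} s is shorter than one minute")
    phase = demodulate_record(record, method=equalization)
    bad = bad_second_mask(phase, cfg.distortion_threshold_k)
    n_minutes = int(phase.duration_s // 60)
    flags = [bool(bad[m * 60:(m + 1) * 60].any()) for m in range(n_minutes)]
    frames = frame_signal(phase, distortion_flags=flags, bad_seconds=bad)
    rows = []
    for m, frame in enumerate(frames):
        est = _estimate_frame(frame, m, cfg)
        if est.valid_rr and est.valid_hr and est.rr_bpm >= est.hr_bpm:
            logger.warning("minute %d: RR (%s) >= HR (%s) — physiologically "
                           "implausible, reported as-is", m, est.rr_bpm, est.hr_bpm)
        rows.append(est)
    return pd.DataFrame([{
        "minute": e.minute_index, "rr_bpm": e.rr_bpm, "hr_bpm": e.hr_bpm,
        "rr_freq_hz": e.rr_freq_hz, "hr_freq_hz": e.hr_freq_hz,
        "valid_rr": e.valid_rr, "valid_hr": e.valid_hr, "distorted": e.distorted,
    } for e in rows])


def _estimate_frame(frame: Frame, minute: int, cfg: BandConfig) -> VitalsEstimate:
    if frame.samples.size == 0:
        return VitalsEstimate(minute, None, None, None, None, False, False, True)
    spec = compute_spectrum(frame)
    rr = estimate_rr(spec, cfg)
    hr = estimate_hr(spec, rr[1] if rr else None, cfg)
    return VitalsEstimate(
        minute_index=minute,
        rr_bpm=rr[0] if rr else None, hr_bpm=hr[0] if hr else None,
        rr_freq_hz=rr[1] if rr else None, hr_freq_hz=hr[1] if hr else None,
        valid_rr=rr is not None, valid_hr=hr is not None,
        distorted=frame.distorted)
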