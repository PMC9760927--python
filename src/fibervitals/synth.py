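"""Synthetic physiological phase signals and 3x3-coupler photodetector outputs.

A fiber-interferometric sensing pad converts chest-wall motion into an
optical path length difference (OPLD) between the measurement and reference
arms, expressed here as a phase in radians. Breathing drives a strong
low-frequency phase excursion with harmonics; the ballistocardiographic
heartbeat adds a weaker component with at least one harmonic; slow baseline
wander and white phase noise complete the model. A 3x3 fiber coupler maps
the phase onto three detector intensities mutually shifted by 2*pi/3:

    u_k(t) = C_k + A_k * cos(phi(t) + (2*pi/3)*k + delta_k),   k = 1, 2, 3

where C_k are channel offsets, A_k amplitudes and delta_k small coupler
phase asymmetries. Everything downstream (demodulation, spectral vital-sign
extraction, agreement statistics) is testable against these simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AliasingError, ArtifactRangeError, InsufficientDataError, InvalidParamsError

__all__ = [
    "SamplingSpec",
    "PhysioParams",
    "CouplerParams",
    "ArtifactSpec",
    "PhaseSeries",
    "CouplerRecord",
    "make_phase_signal",
    "inject_motion_artifact",
    "make_coupler_record",
    "make_paired_dataset",
]

TWO_PI_THIRD = 2.0 * np.pi / 3.0


@dataclass(frozen=True)
class SamplingSpec:
    """Uniform sampling grid: rate in Hz and record length in seconds."""

    fs: float = 250.0
    duration_s: float = 180.0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidParamsError("fs and duration_s must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class PhysioParams:
    """Physiological content of the simulated phase signal.

    Rates are per-minute; amplitudes are phase excursions in radians.
    Harmonic lists hold amplitudes relative to the respective fundamental.
    The cardiac fundamental defaults to a quarter of the breathing one —
    breathing is the stronger mechanical phenomenon — and carries one
    harmonic at relative amplitude 0.4 so the heart-rate rule's
    harmonic-presence criterion is satisfiable. Breathing harmonics default
    to [0.2, 0.1], deliberately below the cardiac fundamental's 0.25 so
    that when a breathing harmonic and the cardiac peak land within one
    spectral bin the merged maximum stays on the cardiac bin.
    """

    rr_bpm: float = 77.0
    hr_bpm: float = 158.0
    breath_amp_rad: float = 2.0
    breath_harmonics: tuple[float, ...] = (0.2, 0.1)
    cardiac_amp_rad: float = 0.5
    cardiac_harmonics: tuple[float, ...] = (0.4,)
    drift_amp_rad: float = 0.5
    drift_freq_hz: float = 0.05
    noise_sd_rad: float = 0.0

    def __post_init__(self):
        amps = (self.breath_amp_rad, self.cardiac_amp_rad, self.drift_amp_rad,
                self.noise_sd_rad, *self.breath_harmonics, *self.cardiac_harmonics)
        if any(a < 0 for a in amps):
            raise InvalidParamsError("amplitudes must be non-negative")
        if self.rr_bpm >= self.hr_bpm:
            raise InvalidParamsError(
                f"rr_bpm ({self.rr_bpm}) must be below hr_bpm ({self.hr_bpm})")

    def highest_frequency_hz(self) -> float:
        """Largest frequency present in the noise-free signal."""
        f_b = self.rr_bpm / 60.0 * (1 + len(self.breath_harmonics))
        f_c = self.hr_bpm / 60.0 * (1 + len(self.cardiac_harmonics))
        return max(f_b, f_c, self.drift_freq_hz)


@dataclass(frozen=True)
class CouplerParams:
    """3x3 coupler channel model: offsets C_k, amplitudes A_k, asymmetries delta_k."""

    C: tuple[float, float, float] = (0.0, 0.0, 0.0)
    A: tuple[float, float, float] = (1.0, 1.0, 1.0)
    delta: tuple[float, float, float] = (0.0, 0.0, 0.0)
    detector_noise_sd: float = 0.0

    def __post_init__(self):
        if len(self.C) != 3 or len(self.A) != 3 or len(self.delta) != 3:
            raise InvalidParamsError("C, A, delta must each have three entries")
        if any(a <= 0 for a in self.A):
            raise InvalidParamsError("channel amplitudes A_k must be positive")
        if self.detector_noise_sd < 0:
            raise InvalidParamsError("detector_noise_sd must be non-negative")


@dataclass(frozen=True)
class ArtifactSpec:
    """A motion-artifact transient: a step or a burst in the phase signal."""

    onset_s: float
    duration_s: float
    magnitude_rad: float
    shape: str = "burst"  # "step" | "burst"

    def __post_init__(self):
        if self.magnitude_rad < 0:
            raise InvalidParamsError("magnitude_rad must be non-negative")
        if self.shape not in ("step", "burst"):
            raise InvalidParamsError(f"unknown artifact shape {self.shape!r}")


@dataclass(frozen=True)
class PhaseSeries:
    """Uniformly sampled phase (OPLD) signal in radians."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise InvalidParamsError("phase values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class CouplerRecord:
    """Three photodetector channel time series on one time base."""

    u: np.ndarray  # shape (3, n)
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 2 or u.shape[0] != 3:
            raise InvalidParamsError("u must have shape (3, n)")
        object.__setattr__(self, "u", u)

    @property
    def n(self) -> int:
        return self.u.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


def make_phase_signal(p: PhysioParams, s: SamplingSpec, seed: int = 0) -> PhaseSeries:
    """Synthesize the phase signal: breathing + cardiac sinusoids with
    harmonics, a slow drift sinusoid, and white Gaussian phase noise.

    Raises AliasingError when fs < 4x the highest simulated harmonic.
    """
    f_max = p.highest_frequency_hz()
    if s.fs < 4.0 * f_max:
        raise AliasingError(
            f"fs={s.fs} Hz below 4x highest simulated frequency {f_max:.3g} Hz")
    t = s.times()
    f_b = p.rr_bpm / 60.0
    f_c = p.hr_bpm / 60.0
    phase = p.breath_amp_rad * np.cos(2 * np.pi * f_b * t)
    for m, rel in enumerate(p.breath_harmonics, start=2):
        phase += p.breath_amp_rad * rel * np.cos(2 * np.pi * m * f_b * t)
    phase += p.cardiac_amp_rad * np.cos(2 * np.pi * f_c * t)
    for m, rel in enumerate(p.cardiac_harmonics, start=2):
        phase += p.cardiac_amp_rad * rel * np.cos(2 * np.pi * m * f_c * t)
    phase += p.drift_amp_rad * np.cos(2 * np.pi * p.drift_freq_hz * t)
    if p.noise_sd_rad > 0:
        rng = np.random.default_rng(seed)
        phase += rng.normal(0.0, p.noise_sd_rad, size=t.size)
    return PhaseSeries(values=phase, fs=s.fs)


def inject_motion_artifact(phase: PhaseSeries, a: ArtifactSpec) -> PhaseSeries:
    """Return a copy of `phase` with a motion transient added.

    "step": phase raised by magnitude_rad for all t >= onset.
    "burst": a Hann-shaped excursion confined to [onset, onset + duration];
    samples outside the support are unchanged.
    """
    if a.onset_s < phase.t0 or a.onset_s + a.duration_s > phase.t0 + phase.duration_s:
        raise ArtifactRangeError(
            f"artifact [{a.onset_s}, {a.onset_s + a.duration_s}] s outside record")
    t = phase.times()
    out = phase.values.copy()
    if a.shape == "step":
        out[t >= a.onset_s] += a.magnitude_rad
    else:
        inside = (t >= a.onset_s) & (t <= a.onset_s + a.duration_s)
        if a.duration_s > 0:
            x = (t[inside] - a.onset_s) / a.duration_s
            out[inside] += a.magnitude_rad * np.sin(np.pi * x) ** 2
    return PhaseSeries(values=out, fs=phase.fs, t0=phase.t0)


def make_coupler_record(phase: PhaseSeries, c: CouplerParams = CouplerParams(),
                        seed: int = 0) -> CouplerRecord:
    """Map a phase signal onto the three coupler outputs.

    u_k = C_k + A_k cos(phi + (2 pi/3) k + delta_k) + detector noise, k=1..3.
    """
    phi = phase.values
    u = np.empty((3, phi.size))
    for i, k in enumerate((1, 2, 3)):
        u[i] = c.C[i] + c.A[i] * np.cos(phi + TWO_PI_THIRD * k + c.delta[i])
    if c.detector_noise_sd > 0:
        rng = np.random.default_rng(seed)
        u += rng.normal(0.0, c.detector_noise_sd, size=u.shape)
    return CouplerRecord(u=u, fs=phase.fs, t0=phase.t0)


def make_paired_dataset(n_subjects: int = 29,
                        truth_rr_range: tuple[float, float] = (39.0, 129.0),
                        truth_hr_range: tuple[float, float] = (122.0, 202.0),
                        efos_noise_sd: float = 2.0,
                        seed: int = 0,
                        n_pairs_per_subject: int = 3) -> pd.DataFrame:
    """Simulate a reference-vs-sensor paired cohort.

    Each subject contributes `n_pairs_per_subject` per-minute pairs per vital
    (RR in breaths/min, HR in beats/min). The reference equals the subject's
    per-minute truth; the sensor value is truth plus Gaussian noise. Subject
    sex and weight are drawn reproducibly from the seed. Returns a long-format
    DataFrame with columns subject, sex, weight_kg, vital, minute, reference,
    efos.
    """
    if n_subjects < 2:
        raise InsufficientDataError("need at least 2 subjects")
    if truth_rr_range[0] >= truth_rr_range[1] or truth_hr_range[0] >= truth_hr_range[1]:
        raise InvalidParamsError("truth ranges must be non-degenerate")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sex = "F" if rng.random() < 10 / 29 else "M"
        weight = float(np.round(rng.uniform(1.5, 4.15), 2))
        for vital, (lo, hi) in (("RR", truth_rr_range), ("HR", truth_hr_range)):
            base = rng.uniform(lo, hi)
            for minute in range(n_pairs_per_subject):
                truth = float(np.round(np.clip(base + rng.normal(0, 2.0), lo, hi)))
                efos = truth + (rng.normal(0, efos_noise_sd) if efos_noise_sd > 0 else 0.0)
                rows.append((f"S{s + 1:02d}", sex, weight, vital, minute, truth, efos))
    return pd.DataFrame(
        rows, columns=["subject", "sex", "weight_kg", "vital", "minute", "reference", "efos"])
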