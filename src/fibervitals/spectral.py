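"""Minute framing and Hamming-windowed magnitude spectra with peak detection.

The demodulated phase is cut into non-overlapping, minute-aligned frames of
60 s (30 s when the minute is distorted by motion), each frame is
mean-removed, multiplied by a periodic Hamming window and transformed by a
one-sided DFT. The 60 s window gives a bin spacing of 1/60 Hz, i.e. exactly
one breath/beat per minute per bin, so on-grid physiological rates fall on
single bins. Peaks are strict 3-point local maxima (leftmost bin on a
plateau), ranked by descending magnitude with the lower frequency first on
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .errors import EmptyFrameError, InsufficientLengthError
from .synth import PhaseSeries

__all__ = ["Frame", "SpectrumFrame", "Peak", "frame_signal", "compute_spectrum",
           "find_local_maxima"]


@dataclass(frozen=True)
class Frame:
    """One analysis window of phase samples (60 s, or 30 s when distorted)."""

    samples: np.ndarray
    fs: float
    start_s: float
    length_s: float
    distorted: bool = False

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.length_s not in (60.0, 30.0):
            raise ValueError("frame length must be 60 or 30 s")


@dataclass(frozen=True)
class SpectrumFrame:
    """One-sided magnitude spectrum of a frame; resolution_hz = 1/length_s."""

    freqs: np.ndarray
    mags: np.ndarray
    resolution_hz: float

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "mags", np.asarray(self.mags, dtype=float))


@dataclass(frozen=True)
class Peak:
    freq_hz: float
    mag: float
    rank: int


def frame_signal(phase: PhaseSeries, distortion_flags=None,
                 bad_seconds=None) -> list[Frame]:
    """Cut a phase record into per-minute frames.

    Clean minutes yield one 60 s frame aligned to the minute boundary. For a
    minute flagged in `distortion_flags`, the earliest 30 s sub-interval
    (aligned to whole seconds) containing no bad second per `bad_seconds` is
    used instead and the frame marked distorted; if no clean 30 s exists the
    frame is emitted empty (and distorted) so downstream marks it invalid.

    `bad_seconds` is an optional per-second boolean mask over the whole
    record (as produced by the distortion detector); without it a flagged
    minute falls back to its first 30 s.
    """
    n_minutes = int(phase.duration_s // 60)
    if n_minutes < 1:
        raise InsufficientLengthError(
            f"record of {phase.duration_s:.1f} s is shorter than one minute")
    if distortion_flags is None:
        distortion_flags = [False] * n_minutes
    fs = phase.fs
    spm = int(round(fs * 60))
    frames: list[Frame] = []
    for m in range(n_minutes):
        start = m * spm
        if not distortion_flags[m]:
            frames.append(Frame(samples=phase.values[start:start + spm], fs=fs,
                                start_s=phase.t0 + m * 60.0, length_s=60.0))
            continue
        sub = _clean_30s_start(m, bad_seconds)
        if sub is None:
            frames.append(Frame(samples=np.empty(0), fs=fs,
                                start_s=phase.t0 + m * 60.0, length_s=30.0,
                                distorted=True))
            continue
        i0 = int(round(sub * fs))
        frames.append(Frame(samples=phase.values[i0:i0 + spm // 2], fs=fs,
                            start_s=phase.t0 + sub, length_s=30.0, distorted=True))
    return frames


def _clean_30s_start(minute: int, bad_seconds) -> float | None:
    """Earliest whole-second start of a clean 30 s window inside `minute`."""
    if bad_seconds is None:
        return minute * 60.0
    bad = np.asarray(bad_seconds, dtype=bool)
    lo, hi = minute * 60, (minute + 1) * 60
    window = bad[lo:hi]
    for s in range(0, 31):
        if s + 30 <= window.size and not window[s:s + 30].any():
            return minute * 60.0 + s
    return None


def compute_spectrum(frame: Frame, zero_pad: int = 1) -> SpectrumFrame:
    """Mean-removed, Hamming-windowed one-sided DFT magnitude of a frame.

    `zero_pad` > 1 interpolates the spectrum onto a grid `zero_pad` times
    finer (the underlying resolution is still 1/length_s).
    """
    x = frame.samples
    if x.size == 0:
        raise EmptyFrameError("cannot transform an empty frame")
    w = get_window("hamming", x.size, fftbins=True)
    xw = (x - x.mean()) * w
    nfft = x.size * int(zero_pad)
    mags = np.abs(np.fft.rfft(xw, n=nfft)) / x.size
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.fs)
    return SpectrumFrame(freqs=freqs, mags=mags, resolution_hz=1.0 / frame.length_s)


def find_local_maxima(spec: SpectrumFrame, f_lo: float, f_hi: float,
                      k: int | None = None) -> list[Peak]:
    """Strict 3-point local maxima of the magnitude spectrum in (f_lo, f_hi].

    A plateau counts once, at its leftmost bin. Peaks are sorted by
    (-magnitude, frequency) — equal magnitudes rank the lower frequency
    first — and truncated to the `k` largest, with ranks 1..k.
    """
    if f_lo >= f_hi:
        raise ValueError("f_lo must be below f_hi")
    m = spec.mags
    # leftmost bin of each plateau that is higher than both flanking values
    rising = np.flatnonzero(np.diff(m) > 0) + 1          # candidates: m[i] > m[i-1]
    peaks_idx = []
    for i in rising:
        j = i
        while j + 1 < m.size and m[j + 1] == m[j]:
            j += 1
        if j + 1 < m.size and m[j + 1] < m[j]:
            peaks_idx.append(i)
    f = spec.freqs
    in_band = [i for i in peaks_idx if f_lo < f[i] <= f_hi]
    in_band.sort(key=lambda i: (-m[i], f[i]))
    if k is not None:
        in_band = in_band[:k]
    return [Peak(freq_hz=float(f[i]), mag=float(m[i]), rank=r + 1)
            for r, i in enumerate(in_band)]
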