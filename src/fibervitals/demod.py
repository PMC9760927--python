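"""Passive homodyne demodulation of 3x3-coupler outputs.

The three coupler channels carry the interferometric phase phi(t) with
mutual 120-degree offsets. After equalizing each channel to zero offset and
unit amplitude, the phase is recovered per sample from the quadrature pair

    y(t) = sqrt(3) * (u2 - u3),      x(t) = u2 + u3 - 2*u1,

as atan2(y, x), which equals phi(t) - pi/3 modulo 2*pi for an ideal coupler
— a single constant offset that is irrelevant to spectral vital-sign
extraction. The two-argument arctangent (rather than a principal-branch
arctan) keeps the full fringe and makes standard unwrapping valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateChannelError
from .synth import CouplerRecord, PhaseSeries

__all__ = ["EqualizationReport", "equalize", "demodulate", "unwrap", "demodulate_record"]

logger = logging.getLogger(__name__)

# A channel whose peak-to-peak span is below this fraction of the largest
# channel's span has not traversed a fringe; its offset/amplitude estimates
# would be meaningless.
FRINGE_UNDERRUN_FRACTION = 0.1


@dataclass(frozen=True)
class EqualizationReport:
    """Estimated per-channel offsets C_k and amplitudes A_k, and the estimator used."""

    C_hat: tuple[float, float, float]
    A_hat: tuple[float, float, float]
    method: str = "minmax"

    def __post_init__(self):
        if any(a <= 0 for a in self.A_hat):
            raise DegenerateChannelError("estimated amplitude must be positive")


def equalize(record: CouplerRecord, method: str = "minmax",
             percentile: float = 0.5) -> tuple[CouplerRecord, EqualizationReport]:
    """Normalize each channel to zero offset and unit amplitude.

    Estimates C_k = (max+min)/2 and A_k = (max-min)/2 per channel over the
    whole record, assuming each channel sweeps at least one full fringe.
    `method="percentile"` replaces min/max by the `percentile` and
    100-`percentile` empirical quantiles, robust to isolated outliers.

    Raises DegenerateChannelError when a channel's peak-to-peak span is
    below 10% of the largest channel's span (the pad saw no modulation on
    that channel).
    """
    u = record.u
    if method == "percentile":
        lo = np.percentile(u, percentile, axis=1)
        hi = np.percentile(u, 100.0 - percentile, axis=1)
    elif method == "minmax":
        lo = u.min(axis=1)
        hi = u.max(axis=1)
    else:
        raise ValueError(f"unknown equalization method {method!r}")
    ptp = hi - lo
    if np.any(ptp < FRINGE_UNDERRUN_FRACTION * ptp.max()) or ptp.max() == 0:
        bad = [k + 1 for k in range(3) if ptp[k] < FRINGE_UNDERRUN_FRACTION * ptp.max()]
        raise DegenerateChannelError(
            f"channel(s) {bad or [1, 2, 3]} nearly constant (fringe underrun)")
    C_hat = (hi + lo) / 2.0
    A_hat = ptp / 2.0
    out = CouplerRecord(u=(u - C_hat[:, None]) / A_hat[:, None], fs=record.fs, t0=record.t0)
    report = EqualizationReport(C_hat=tuple(C_hat), A_hat=tuple(A_hat), method=method)
    return out, report


def demodulate(record: CouplerRecord) -> PhaseSeries:
    """Recover the wrapped phase in (-pi, pi] from an equalized record.

    Where numerator and denominator both vanish (a singular point), the
    previous sample's value is held and a warning is logged.
    """
    u1, u2, u3 = record.u
    y = np.sqrt(3.0) * (u2 - u3)
    x = u2 + u3 - 2.0 * u1
    wrapped = np.arctan2(y, x)
    eps = 1e-12
    singular = (np.abs(y) < eps) & (np.abs(x) < eps)
    if np.any(singular):
        logger.warning("demod: %d singular point(s); holding previous sample",
                       int(singular.sum()))
        idx = np.flatnonzero(singular)
        for i in idx:
            wrapped[i] = wrapped[i - 1] if i > 0 else 0.0
    return PhaseSeries(values=wrapped, fs=record.fs, t0=record.t0)


def unwrap(wrapped: PhaseSeries) -> PhaseSeries:
    """Remove 2*pi jumps so successive differences never exceed pi in magnitude."""
    return PhaseSeries(values=np.unwrap(wrapped.values), fs=wrapped.fs, t0=wrapped.t0)


def demodulate_record(record: CouplerRecord, method: str = "minmax") -> PhaseSeries:
    """Convenience chain: equalize -> demodulate -> unwrap."""
    eq, _ = equalize(record, method=method)
    return unwrap(demodulate(eq))
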