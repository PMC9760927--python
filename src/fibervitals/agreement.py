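"""Method-agreement and group-comparison statistics.

Agreement between a reference monitor and the fiber-optic sensor is
summarized nonparametrically: differences (reference - sensor) by median and
interquartile range, limits of agreement as the empirical 2.5% and 97.5%
quantiles of the differences, reliability by the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation ICC(2,1) with
its F-based 95% confidence interval, and a paired Wilcoxon signed-rank test
for systematic bias. Group comparisons (e.g. by sex) use the Mann-Whitney U
test, the Brown-Forsythe variant of Levene's test for spread, and Spearman's
rank correlation for monotone association.

Small-sample Wilcoxon and Mann-Whitney p-values are exact by full
enumeration, with zero differences dropped and mid-ranks for ties; larger
samples use the normal approximation with continuity (and tie) correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["AgreementReport", "paired_differences", "bland_altman", "icc",
           "wilcoxon_paired", "mann_whitney", "levene", "spearman", "agreement_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementReport:
    median_diff: float
    iqr: tuple[float, float]
    loa: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    wilcoxon_p: float
    n_pairs: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iqr"] = list(d["iqr"])
        d["loa"] = list(d["loa"])
        d["icc_ci"] = list(d["icc_ci"])
        return d


def paired_differences(pairs: pd.DataFrame, vital: str | None = None,
                       per_subject_median: bool = False) -> pd.DataFrame:
    """Extract (reference, efos) columns for one vital from a long-format
    table, optionally collapsing the repeated per-minute pairs of each
    subject to their median (avoids pseudo-replication in paired tests)."""
    df = pairs
    if vital is not None:
        df = df[df["vital"] == vital]
    if df.empty:
        raise InsufficientDataError(f"no rows for vital {vital!r}")
    if per_subject_median:
        df = df.groupby("subject", as_index=False)[["reference", "efos"]].median()
    return df


def bland_altman(reference, efos) -> dict:
    """Nonparametric Bland-Altman summary of d = reference - efos.

    Returns median, (Q1, Q3) and the empirical 2.5%/97.5% quantiles of the
    differences (linear-interpolation quantiles).
    """
    reference = np.asarray(reference, dtype=float)
    efos = np.asarray(efos, dtype=float)
    if reference.size < 3 or reference.size != efos.size:
        raise InsufficientDataError("need at least 3 paired values")
    d = reference - efos
    q1, q3 = np.quantile(d, [0.25, 0.75])
    lo, hi = np.quantile(d, [0.025, 0.975])
    return {"median_diff": float(np.median(d)), "iqr": (float(q1), float(q3)),
            "loa": (float(lo), float(hi)), "n_pairs": int(d.size)}


def icc(reference, efos, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the subjects x methods mean-squares decomposition; the
    confidence interval follows the F-based formula of Shrout & Fleiss (as
    formulated by McGraw & Wong). Returns (estimate, ci_lo, ci_hi).
    """
    y = np.column_stack([np.asarray(reference, float), np.asarray(efos, float)])
    n, k = y.shape
    if n < 5:
        raise InsufficientDataError("need at least 5 subjects for ICC")
    if np.array_equal(y[:, 0], y[:, 1]) and np.ptp(y[:, 0]) > 0:
        return 1.0, 1.0, 1.0
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        logger.warning("icc: no between-subject variance beyond error; estimate 0")
        return 0.0, 0.0, 0.0
    est = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0:  # perfect agreement: CI collapses
        return 1.0, 1.0, 1.0
    fj = msc / mse
    a = k * est / (n * (1 - est))
    b = 1 + k * est * (n - 1) / (n * (1 - est))
    v = (a * fj + b) ** 2 / (a ** 2 * fj ** 2 / (k - 1) + b ** 2 / (n - 1))
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(est), float(lo), float(hi)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic programming
    over all 2^n sign assignments (ranks may be mid-ranks in 0.5 steps)."""
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[:w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_paired(reference, efos=None, exact_max_n: int = 20) -> float:
    """Two-sided paired Wilcoxon signed-rank test.

    Accepts either precomputed differences or the (reference, efos) pair.
    Zero differences are dropped; ties take mid-ranks. Exact enumeration for
    n <= exact_max_n, otherwise the normal approximation with continuity
    correction. All-zero differences return p = 1 with a warning.
    """
    d = np.asarray(reference, dtype=float)
    if efos is not None:
        d = d - np.asarray(efos, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_paired: all differences zero; p = 1")
        return 1.0
    if d.size <= exact_max_n:
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        return _signed_rank_exact_p(ranks, w_plus)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method="approx")
    return float(res.pvalue)


def _mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p for U by enumerating all group-A position choices."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    m, total = a.size, pooled.size
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = np.array([ranks[list(idx)].sum() - m * (m + 1) / 2
                   for idx in itertools.combinations(range(total), m)])
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def mann_whitney(group_a, group_b, exact_max_n: int = 12) -> float:
    """Two-sided Mann-Whitney U test; exact enumeration when the pooled size
    is at most exact_max_n, else normal approximation with tie correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if a.size + b.size <= exact_max_n:
        return _mann_whitney_exact_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def levene(group_a, group_b) -> float:
    """Brown-Forsythe test for equal spread: one-way F test on absolute
    deviations from each group's median. Degenerate input (no variation at
    all) returns p = 1 with a warning."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("levene: all values identical; statistic undefined, p = 1")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.levene(a, b, center="median")
    return 1.0 if np.isnan(p) else float(p)


def spearman(x, y, confidence: float = 0.95) -> tuple[float, float, float, float]:
    """Spearman's rho with a Fisher-z confidence interval.

    rho is the Pearson correlation of mid-ranks; the two-sided p uses the t
    approximation; the CI uses Fisher's z transform with variance
    1.06/(n - 3). Returns (rho, ci_lo, ci_hi, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - (1 - confidence) / 2) * np.sqrt(1.06 / (n - 3))
    return float(rho), float(np.tanh(z - half)), float(np.tanh(z + half)), float(p)


def agreement_report(pairs: pd.DataFrame, vital: str,
                     per_subject_median_tests: bool = False) -> AgreementReport:
    """Assemble the full agreement battery for one vital.

    Bland-Altman summaries use every pair; the ICC and the paired Wilcoxon
    optionally operate on per-subject medians to avoid treating repeated
    minutes as independent subjects.
    """
    df = paired_differences(pairs, vital)
    ba = bland_altman(df["reference"], df["efos"])
    dfm = paired_differences(pairs, vital, per_subject_median=per_subject_median_tests)
    est, lo, hi = icc(dfm["reference"], dfm["efos"])
    p = wilcoxon_paired(dfm["reference"], dfm["efos"])
    return AgreementReport(median_diff=ba["median_diff"], iqr=ba["iqr"],
                           loa=ba["loa"], icc=est, icc_ci=(lo, hi),
                           wilcoxon_p=p, n_pairs=ba["n_pairs"])
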