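import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fibervitals import (agreement_report, bland_altman, icc, levene, make_paired_dataset,
                         mann_whitney, spearman, wilcoxon_paired)
from fibervitals.errors import InsufficientDataError


def brute_force_icc21(y):
    """Independent oracle: ICC(2,1) from explicit ANOVA sums of squares."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    msr = k * sum((y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_force_signed_rank_p(d):
    """Enumerate all sign assignments of |d|'s mid-ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(ranks))]
    ws = np.asarray(ws)
    return min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))


class TestBlandAltman:
    def test_identical_methods_collapse_to_zero(self):
        x = np.array([10.0, 12.0, 15.0, 20.0])
        r = bland_altman(x, x)
        assert r["median_diff"] == 0.0
        assert r["loa"] == (0.0, 0.0)

    def test_median_of_even_count_averages_middle_pair(self):
        d = np.array([-1.0, 1.0, 2.0, 4.0])
        r = bland_altman(d, np.zeros(4))
        assert r["median_diff"] == pytest.approx(1.5)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(100, 10, 40)
        efos = ref + rng.normal(0, 3, 40)
        base = bland_altman(ref, efos)
        shifted = bland_altman(ref + 7.0, efos)
        assert shifted["median_diff"] == pytest.approx(base["median_diff"] + 7.0)
        assert shifted["loa"][0] == pytest.approx(base["loa"][0] + 7.0)
        assert shifted["loa"][1] == pytest.approx(base["loa"][1] + 7.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1, 2], [1, 2])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_loa_brackets_median(self, diffs):
        r = bland_altman(np.asarray(diffs), np.zeros(len(diffs)))
        assert r["loa"][0] <= r["median_diff"] <= r["loa"][1]


class TestICC:
    def test_perfect_agreement_gives_one(self):
        x = np.array([10.0, 12.0, 15.0, 20.0, 25.0])
        assert icc(x, x)[0] == 1.0

    def test_matches_brute_force_anova(self):
        y = np.array([[9., 8.], [1., 2.], [8., 6.], [6., 7.], [7., 5.], [3., 4.]])
        est, lo, hi = icc(y[:, 0], y[:, 1])
        assert est == pytest.approx(brute_force_icc21(y), abs=1e-10)
        assert lo <= est <= hi

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(5)
        ref = rng.normal(150, 20, 12)
        efos = ref + rng.normal(0, 5, 12)
        est, lo, hi = icc(ref, efos)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["ref", "efos"], 12),
            "ratings": np.column_stack([ref, efos]).ravel()})
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings").set_index("Type")
        label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        row = table.loc[label]
        assert est == pytest.approx(row["ICC"], abs=1e-8)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        # pingouin reports the CI rounded to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(row[ci_col]), abs=6e-3)

    def test_icc_rises_as_noise_falls(self):
        vals = []
        for sd in (8.0, 2.0, 0.5):
            df = make_paired_dataset(n_subjects=25, efos_noise_sd=sd, seed=11)
            rr = df[df.vital == "RR"].groupby("subject")[["reference", "efos"]].median()
            vals.append(icc(rr["reference"], rr["efos"])[0])
        assert vals[0] < vals[1] < vals[2]

    def test_no_between_subject_variance_gives_zero(self):
        ref = np.full(6, 5.0)
        efos = np.array([4.0, 6.0, 4.0, 6.0, 4.0, 6.0])
        assert icc(ref, efos)[0] == 0.0


class TestWilcoxonPaired:
    def test_all_positive_n5_exact(self):
        assert wilcoxon_paired([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(0.0625, abs=1e-12)

    def test_matches_brute_force_enumeration_with_ties(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 0.0, 5.0])
        assert wilcoxon_paired(d) == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_symmetric_differences_give_large_p(self):
        d = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        assert wilcoxon_paired(d) > 0.5

    def test_all_zero_differences_give_p_one(self):
        assert wilcoxon_paired(np.zeros(10)) == 1.0

    def test_exact_and_approximate_agree_moderate_n(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.4, 1.0, 15)
        p_exact = wilcoxon_paired(d, exact_max_n=20)
        p_approx = wilcoxon_paired(d, exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.02

    def test_type_one_error_near_nominal(self):
        """Null calibration: rejection rate at alpha=0.05 over 1000 replicates."""
        rng = np.random.default_rng(12345)
        rejections = sum(
            wilcoxon_paired(rng.normal(0, 1, 87)) < 0.05 for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


class TestMannWhitney:
    def test_disjoint_small_groups_exact(self):
        assert mann_whitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_near_one(self):
        assert mann_whitney([5, 6, 7, 8], [5, 6, 7, 8]) > 0.9

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert mann_whitney(a, b) == pytest.approx(mann_whitney(10 * a, 10 * b))

    def test_order_invariance(self):
        a = [3.0, 1.0, 4.0, 1.5]
        b = [9.0, 2.0, 6.0, 5.0]
        assert mann_whitney(a, b) == pytest.approx(mann_whitney(a[::-1], b[::-1]))


class TestLevene:
    def test_equal_spread_gives_large_p(self):
        rng = np.random.default_rng(4)
        assert levene(rng.normal(0, 1, 30), rng.normal(5, 1, 30)) > 0.05

    def test_tenfold_scale_difference_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 10, 20)
        assert levene(a, b) < 0.05

    def test_location_shift_does_not_change_statistic(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 2, 15)
        assert levene(a, b) == pytest.approx(levene(a + 100, b))

    def test_degenerate_input_gives_p_one(self):
        assert levene([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]) == 1.0


class TestSpearman:
    def test_monotone_increasing_gives_rho_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rho, lo, hi, p = spearman(x, np.exp(x))
        assert rho == 1.0

    def test_monotone_decreasing_gives_rho_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, -x)[0] == -1.0

    def test_tied_fixture_matches_midrank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 7.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, 30)
        rho, lo, hi, p = spearman(x, y)
        assert lo < rho < hi

    def test_constant_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestAgreementReport:
    def test_zero_noise_cohort_perfect_agreement(self):
        pairs = make_paired_dataset(n_subjects=10, efos_noise_sd=0.0, seed=0)
        for vital in ("RR", "HR"):
            rep = agreement_report(pairs, vital)
            assert rep.icc == 1.0
            assert rep.median_diff == 0.0
            assert rep.loa == (0.0, 0.0)

    def test_report_fields_and_invariants(self):
        pairs = make_paired_dataset(n_subjects=29, efos_noise_sd=2.0, seed=1)
        rep = agreement_report(pairs, "HR", per_subject_median_tests=True)
        assert rep.n_pairs == 87
        assert rep.loa[0] <= rep.median_diff <= rep.loa[1]
        assert -1 <= rep.icc <= 1
        assert 0 <= rep.wilcoxon_p <= 1

    def test_subject_order_invariance(self):
        pairs = make_paired_dataset(n_subjects=12, efos_noise_sd=3.0, seed=2)
        shuffled = pairs.sample(frac=1.0, random_state=0)
        a = agreement_report(pairs, "RR")
        b = agreement_report(shuffled, "RR")
        assert a.icc == pytest.approx(b.icc, abs=1e-12)
        assert a.median_diff == pytest.approx(b.median_diff)
        assert a.wilcoxon_p == pytest.approx(b.wilcoxon_p, abs=1e-12)
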