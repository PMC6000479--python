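"""Test-retest reliability: ANOVA decomposition, ICC(A,1), SEM/SDC,
practice effects, correlations, and the per-measure report."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acsnorms import (
    Direction,
    InsufficientDataError,
    SDC_FACTOR,
    ValidationError,
    VarianceDecomposition,
    anova_decompose,
    icc_absolute_agreement,
    practice_test,
    reliability_report,
    retest_correlation,
    sdc,
    sdc_group,
    sem_from_decomp,
)
from acsnorms.reliability import acs_reference_reliability


def oracle_decompose(arr):
    """Definitional sums-of-squares oracle (explicit loops)."""
    arr = np.asarray(arr, dtype=float)
    n, k = arr.shape
    grand = sum(arr[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(arr[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(arr[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum((arr[i, j] - row[i] - col[j] + grand) ** 2
                 for i in range(n) for j in range(k))
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def oracle_icc_a1(arr):
    msr, msc, mse = oracle_decompose(arr)
    n, k = np.asarray(arr).shape
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestAnovaDecompose:
    def test_perfect_agreement(self):
        d = anova_decompose([(1, 1), (2, 2), (5, 5), (9, 9)])
        assert d.ms_cols == 0.0 and d.ms_error == 0.0
        assert d.ms_rows > 0

    def test_constant_shift_is_pure_systematic_error(self):
        d = anova_decompose([(1, 2), (3, 4), (5, 6), (7, 8)])
        assert d.ms_error == pytest.approx(0.0, abs=1e-12)
        assert d.ms_cols > 0

    def test_matches_bruteforce_oracle(self):
        arr = [(1, 2), (3, 4), (5, 6), (7, 8)]
        d = anova_decompose(arr)
        msr, msc, mse = oracle_decompose(arr)
        assert d.ms_rows == pytest.approx(msr, abs=1e-12)
        assert d.ms_cols == pytest.approx(msc, abs=1e-12)
        assert d.ms_error == pytest.approx(mse, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            anova_decompose([(1, 2), (3, 4)])


class TestIcc:
    def test_perfect_agreement_is_one(self):
        d = anova_decompose([(1, 1), (2, 2), (3, 3)])
        assert icc_absolute_agreement(d) == 1.0

    def test_absolute_agreement_penalizes_shift(self):
        arr = [(1.0, 2.1), (3.1, 4.0), (5.0, 6.2), (7.2, 8.1), (9.0, 10.2)]
        d = anova_decompose(arr)
        icc_abs = icc_absolute_agreement(d)
        # consistency-type ICC ignores the occasion shift
        icc_cons = (d.ms_rows - d.ms_error) / (d.ms_rows + d.ms_error)
        assert icc_abs < icc_cons

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=10))
    def test_formula_equals_oracle(self, pairs):
        """ICC(A,1) from mean squares equals the definitional brute-force
        computation on every random n<=10, k=2 table."""
        arr = np.array(pairs)
        d = anova_decompose(arr)
        denom = d.ms_rows + d.ms_error + (2 / d.n_subjects) * \
            (d.ms_cols - d.ms_error)
        if abs(denom) < 1e-9:
            return  # degenerate: defined as 1 with warning
        assert icc_absolute_agreement(d) == pytest.approx(
            oracle_icc_a1(arr), rel=1e-9, abs=1e-9)

    def test_against_pingouin(self):
        """Independent cross-check of the ICC variant against pingouin's
        ICC2 (single random raters, absolute agreement)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2018)
        for _ in range(5):
            n = rng.integers(10, 40)
            s1 = rng.normal(50, 10, n)
            s2 = 0.8 * s1 + rng.normal(5, 6, n)
            data = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile([1, 2], n),
                "scores": np.column_stack([s1, s2]).ravel()})
            ref = pingouin.intraclass_corr(data, targets="targets",
                                           raters="raters", ratings="scores")
            icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            ours = icc_absolute_agreement(
                anova_decompose(np.column_stack([s1, s2])))
            assert ours == pytest.approx(icc2, abs=1e-6)


class TestPracticeTest:
    def test_identical_occasions(self):
        res = practice_test([(3, 3), (5, 5), (7, 7)])
        assert res.t_stat == 0.0 and not res.practice_effect

    def test_detects_simulated_shift(self):
        """n=240 pairs with mean difference 2.35 and SD of differences
        giving t ~ 5.4 (the Connect the Dots I pattern)."""
        rng = np.random.default_rng(20181)
        n, mean_d, t_target = 240, 2.35, 5.43
        sd_d = mean_d * math.sqrt(n) / t_target
        s1 = rng.normal(34.83, 9.4, n)
        diffs = mean_d + sd_d * rng.standard_normal(n)
        diffs = (diffs - diffs.mean()) / diffs.std(ddof=1) * sd_d + mean_d
        res = practice_test(np.column_stack([s1, s1 - diffs]),
                            direction=Direction.LOWER_IS_BETTER)
        assert res.t_stat == pytest.approx(t_target, abs=1e-6)
        assert res.df == n - 1
        assert res.practice_effect

    def test_small_shift_in_wide_spread_not_significant(self):
        """The Reaction Speed pattern: tiny mean shift relative to the
        spread of differences yields no practice effect."""
        rng = np.random.default_rng(20182)
        n = 241
        s1 = rng.normal(308.88, 44.6, n)
        s2 = s1 + rng.normal(1.6, 36.0, n)
        res = practice_test(np.column_stack([s1, s2]),
                            direction=Direction.LOWER_IS_BETTER)
        assert not res.practice_effect

    def test_significant_decline_is_not_practice(self):
        """A significant change in the *worse* direction is not a practice
        effect when the measure's direction is known."""
        rng = np.random.default_rng(20183)
        n = 100
        s1 = rng.normal(50, 5, n)
        s2 = s1 - 4.0 + rng.normal(0, 1, n)  # scores drop
        res = practice_test(np.column_stack([s1, s2]),
                            direction=Direction.HIGHER_IS_BETTER)
        assert res.p_value < 0.001 and not res.practice_effect

    def test_zero_variance_of_differences(self):
        res = practice_test([(1, 3), (2, 4), (5, 7)])  # constant diff -2
        assert math.isnan(res.p_value) and not res.practice_effect


class TestSemSdc:
    def test_sem_inverts_published_square(self):
        d = VarianceDecomposition(ms_rows=100.0, ms_cols=1.0,
                                  ms_error=22.6576, n_subjects=240,
                                  k_occasions=2)
        assert sem_from_decomp(d) == pytest.approx(4.76, abs=1e-12)

    @pytest.mark.parametrize("sem, expected", [
        (0.0, 0.0), (0.90, 2.4947), (4.76, 13.1940)])
    def test_sdc_arithmetic(self, sem, expected):
        assert sdc(sem) == pytest.approx(expected, abs=5e-5)

    def test_published_group_sdc_values(self):
        """Group SDC recomputed from published SEM, n, means, and practice
        flags matches the published table at 2 decimals."""
        expected = {"ConnectTheDotsI": 1.00, "ConnectTheDotsII": 1.89,
                    "WordlistLearning": 1.36, "WordlistDelayedRecall": 0.72,
                    "WordlistRecognition": 0.16, "PlaceTheBeads": 2.93,
                    "BoxTapping": 0.30, "TotalScore": 0.01}
        refs = acs_reference_reliability()
        for measure, value in expected.items():
            assert round(refs[measure].group_sdc(), 2) == value, measure

    def test_trivial_group_sdc(self):
        assert sdc_group(0.0, 1) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(sem1=st.floats(0, 50), sem2=st.floats(0, 50),
           n1=st.integers(1, 500), n2=st.integers(1, 500))
    def test_group_sdc_monotone(self, sem1, sem2, n1, n2):
        """sdc_group decreases in n and increases in sem."""
        lo_sem, hi_sem = sorted([sem1, sem2])
        lo_n, hi_n = sorted([n1, n2])
        assert sdc_group(lo_sem, lo_n) >= sdc_group(lo_sem, hi_n)
        assert sdc_group(lo_sem, lo_n) <= sdc_group(hi_sem, lo_n)


class TestRetestCorrelation:
    def test_linear_pairs(self):
        pairs = [(i, 2 * i + 1) for i in range(10)]
        for method in ("pearson", "spearman"):
            r, kind = retest_correlation(pairs, method=method)
            assert r == pytest.approx(1.0)
            assert kind == method

    def test_monotone_nonlinear_prefers_rank(self):
        x = np.linspace(1, 5, 30)
        pairs = np.column_stack([x, x ** 3])
        rho, _ = retest_correlation(pairs, method="spearman")
        r, _ = retest_correlation(pairs, method="pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_auto_selects_spearman_for_skewed_scores(self):
        rng = np.random.default_rng(20184)
        x = rng.lognormal(0, 1, 300)
        pairs = np.column_stack([x, x + rng.normal(0, 0.1, 300)])
        _, kind = retest_correlation(pairs, method="auto")
        assert kind == "spearman"

    def test_recovers_bivariate_normal_rho(self):
        rng = np.random.default_rng(20185)
        n, rho = 2000, 0.75
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        r, kind = retest_correlation(np.column_stack([z1, z2]))
        assert kind == "pearson"
        assert r == pytest.approx(rho, abs=0.03)


class TestReliabilityReport:
    def test_missing_occasion_two_is_an_error(self, battery, small_table):
        occ1 = small_table.df[small_table.df["occasion"] == 1]
        from acsnorms import ScoreTable
        with pytest.raises(ValidationError, match="occasion"):
            reliability_report(ScoreTable(occ1), battery)

    def test_excluded_participant_drops_from_pairs(self, battery, cohort):
        table = cohort.scores
        measure = "BoxTapping"
        n_before = len(table.pairs(measure))
        pid = table.pairs(measure).index[0]
        flagged = table.with_exclusions([(pid, 2, measure, "manual")])
        results = {r.measure: r for r in reliability_report(
            flagged, battery, include_composite=False)}
        assert results[measure].n_pairs == n_before - 1

    def test_report_is_deterministic(self, battery, cohort):
        r1 = reliability_report(cohort.scores, battery)
        r2 = reliability_report(cohort.scores, battery)
        assert r1 == r2

    def test_sem_bounded_by_pooled_sd(self, battery, cohort):
        """When ICC >= 0, within-person error cannot exceed the pooled
        between+within spread."""
        for r in reliability_report(cohort.scores, battery):
            if r.icc >= 0:
                pooled = math.sqrt((r.sd1 ** 2 + r.sd2 ** 2) / 2)
                assert r.sem <= pooled * (1 + 1e-9)

    def test_composite_present_with_reduced_n(self, battery, cohort):
        results = {r.measure: r for r in reliability_report(
            cohort.scores, battery)}
        assert "TotalScore" in results
        total = results["TotalScore"]
        max_component_n = max(r.n_pairs for m, r in results.items()
                              if m != "TotalScore")
        assert total.n_pairs <= max_component_n
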