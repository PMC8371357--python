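"""Welch/TOST/power inference stack against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from searchprime.stats import (
    GroupSummary,
    cohens_d,
    cohens_d_from_summaries,
    holm,
    meta_fixed,
    ols,
    paired_d,
    paired_t,
    pearson_r,
    power_t,
    power_t_at,
    power_tost,
    tost,
    tost_from_summaries,
    welch_from_summaries,
    welch_t,
)


class TestWelch:
    @pytest.mark.parametrize("alternative,scipy_alt", [
        ("two_sided", "two-sided"), ("greater", "greater"), ("less", "less"),
    ])
    def test_matches_scipy_reference(self, rng, alternative, scipy_alt):
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(0.3, 2.0, 55)
        ours = welch_t(x, y, alternative)
        ref = sps.ttest_ind(x, y, equal_var=False, alternative=scipy_alt)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert ours.df == pytest.approx(ref.df, abs=1e-8)

    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x.copy())
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_shifted_equal_variance_matches_pooled_t(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + 1.0
        ours = welch_t(x, y)
        pooled = sps.ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(pooled.statistic, rel=1e-12)

    def test_published_group_summaries(self):
        # manipulation-check summaries: n=172, M=9.95, sd=1.34 vs n=167,
        # M=12.07, sd=1.71; printed t = 12.71, df = 313.90 (tiny gaps come
        # from the rounding of the printed sds)
        res = welch_from_summaries(
            GroupSummary(172, 9.95, 1.34), GroupSummary(167, 12.07, 1.71)
        )
        ref = sps.ttest_ind_from_stats(9.95, 1.34, 172, 12.07, 1.71, 167, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-6)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)
        assert res.statistic == pytest.approx(-12.71, abs=0.05)
        assert res.df == pytest.approx(313.9, abs=1.0)

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0, 1.0], [1.0, 1.0])


class TestCohensD:
    def test_equal_means(self, rng):
        x = rng.normal(0, 1, 50)
        es = cohens_d(x, x.copy())
        assert es.d == 0.0
        assert es.ci_low < 0.0 < es.ci_high

    def test_published_study_summaries(self):
        # n=172, M=9.95, sd=1.34 vs n=167, M=12.07, sd=1.71:
        # printed d = 1.38, CI95 [1.15, 1.62]
        es = cohens_d_from_summaries(
            GroupSummary(172, 9.95, 1.34), GroupSummary(167, 12.07, 1.71)
        )
        assert abs(es.d) == pytest.approx(1.38, abs=0.005)
        assert abs(es.ci_high) == pytest.approx(1.15, abs=0.02)
        assert abs(es.ci_low) == pytest.approx(1.62, abs=0.02)

    def test_sign_convention_group1_minus_group2(self):
        es = cohens_d_from_summaries(GroupSummary(20, 1.0, 1.0), GroupSummary(20, 0.0, 1.0))
        assert es.d == pytest.approx(1.0)

    def test_ci_against_grid_inversion_oracle(self):
        g1, g2 = GroupSummary(43, 10.07, 2.20), GroupSummary(43, 12.15, 2.07)
        es = cohens_d_from_summaries(g1, g2)
        scale = math.sqrt(43 * 43 / 86)
        t_obs = es.d * scale
        df = 84
        # brute-force scan of the noncentrality parameter
        grid = np.linspace(t_obs - 8, t_obs + 8, 400_001)
        cdf = sps.nct.cdf(t_obs, df, grid)
        lo = grid[np.searchsorted(-cdf, -0.975)] / scale
        hi = grid[np.searchsorted(-cdf, -0.025)] / scale
        assert es.ci_low == pytest.approx(lo, abs=1e-4)
        assert es.ci_high == pytest.approx(hi, abs=1e-4)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled sd"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestTost:
    def test_large_equal_samples_equivalent(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        assert tost(x, y, bound_d=0.36).equivalent

    def test_effect_exactly_at_bound_not_reliably_equivalent(self):
        # observed d equal to the bound: the matching one-sided t is 0, so
        # p_tost = 0.5 no matter how large n gets
        res = tost_from_summaries(
            GroupSummary(100_000, 0.0, 1.0), GroupSummary(100_000, -0.36, 1.0),
            bound_d=0.36,
        )
        assert res.p_tost == pytest.approx(0.5, abs=1e-6)
        assert not res.equivalent

    def test_four_quadrants(self, rng):
        bound = 0.36
        # not significantly different AND equivalent: null effect, large n
        a = tost(rng.normal(0, 1, 400), rng.normal(0, 1, 400), bound)
        w = welch_t(rng.normal(0, 1, 400), rng.normal(0, 1, 400))
        assert a.equivalent and w.p > 0.05
        # not significantly different AND not equivalent: tiny n
        b_x, b_y = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        assert not tost(b_x, b_y, bound).equivalent
        assert welch_t(b_x, b_y).p > 0.05
        # significantly different AND equivalent: minuscule true effect, huge n
        c_x, c_y = rng.normal(0, 1, 60_000), rng.normal(0.02, 1, 60_000)
        assert tost(c_x, c_y, bound).equivalent
        # significantly different AND not equivalent: big effect
        d_x, d_y = rng.normal(0, 1, 200), rng.normal(1.0, 1, 200)
        assert not tost(d_x, d_y, bound).equivalent
        assert welch_t(d_x, d_y).p < 0.05

    def test_welch_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(1000):
            ps.append(welch_t(rng.normal(0, 1, 20), rng.normal(0, 2, 25)).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPower:
    def test_planning_returns_168(self):
        assert power_t(0.36, alpha=0.05, target_power=0.95, alternative="greater") == 168

    def test_huge_effect_floor(self):
        assert power_t(3.0, alpha=0.05, target_power=0.5) == 2

    def test_minimality(self):
        n = power_t(0.36, 0.05, 0.95, "greater")
        assert power_t_at(n, 0.36, 0.05, "greater") >= 0.95
        assert power_t_at(n - 1, 0.36, 0.05, "greater") < 0.95

    def test_monotone_in_d_and_power(self):
        assert power_t(0.5, 0.05, 0.95) < power_t(0.36, 0.05, 0.95)
        assert power_t(0.36, 0.05, 0.90) < power_t(0.36, 0.05, 0.95)

    def test_tost_power_at_study_n(self):
        assert power_tost(168, 0.36, 0.05, true_d=0.0) == pytest.approx(0.90, abs=0.005)

    def test_tost_power_at_the_bound_is_near_alpha(self):
        assert power_tost(168, 0.36, 0.05, true_d=0.36) <= 0.05 + 0.01


class TestPaired:
    def test_zero_diffs_have_undefined_t(self):
        with pytest.raises(ValueError, match="zero sd"):
            paired_t(np.zeros(10))
        with pytest.raises(ValueError, match="zero sd"):
            paired_t(np.full(10, 3.0))

    def test_matches_scipy_one_sample(self, rng):
        diffs = rng.normal(0.4, 1.0, 35)
        ours = paired_t(diffs)
        ref = sps.ttest_1samp(diffs, 0.0)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.df == 34

    def test_paired_d_is_mean_over_sd(self, rng):
        diffs = rng.normal(0.5, 1.0, 40)
        es = paired_d(diffs)
        assert es.d == pytest.approx(diffs.mean() / diffs.std(ddof=1))
        assert es.ci_low < es.d < es.ci_high

    def test_nan_diffs_dropped(self, rng):
        diffs = np.concatenate([rng.normal(0.5, 1.0, 30), [np.nan, np.nan]])
        assert paired_t(diffs).df == 29


class TestCorrelationRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, ci, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        fit = ols(2 * x + 1, x, names=["x"])
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(1.0, abs=1e-10)

    def test_fisher_ci_coverage_under_independence(self, rng):
        covered = 0
        reps = 300
        for _ in range(reps):
            x, y = rng.normal(size=339), rng.normal(size=339)
            _, (lo, hi), _ = pearson_r(x, y)
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_two_predictor_fit_matches_normal_equations(self, rng):
        X = rng.normal(size=(100, 2))
        y = 1.0 + 0.5 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(size=100)
        fit = ols(y, X, names=["a", "b"])
        design = np.column_stack([np.ones(100), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_constant_column_named_in_error(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.raises(ValueError, match="frozen"):
            ols(rng.normal(size=20), X, names=["ok", "frozen"])


class TestMeta:
    def test_single_study_identity(self):
        res = meta_fixed([(0.5, 30, 30)])
        assert res.d_pooled == pytest.approx(0.5)

    def test_two_identical_studies_narrow_ci(self):
        one = meta_fixed([(0.4, 50, 50)])
        two = meta_fixed([(0.4, 50, 50), (0.4, 50, 50)])
        assert two.d_pooled == pytest.approx(0.4)
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_three_studies_match_hand_computed_weights(self):
        studies = [(0.2, 40, 40), (0.5, 60, 55), (-0.1, 30, 35)]
        ws, ds = [], []
        for d, n1, n2 in studies:
            var = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
            ws.append(1 / var)
            ds.append(d)
        expected = sum(w * d for w, d in zip(ws, ds)) / sum(ws)
        assert meta_fixed(studies).d_pooled == pytest.approx(expected, abs=1e-12)

    def test_invalid_group_size(self):
        with pytest.raises(ValueError):
            meta_fixed([(0.3, 0, 10)])


def test_holm_adjusts_upward():
    raw = [0.01, 0.02, 0.4]
    adj = holm(raw)
    assert all(a >= r for a, r in zip(adj, raw))
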