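"""Metric arithmetic against hand computations, identities over seeded
series vs an independent plain-Python implementation, and the
normality-gated branch logic of the group comparisons."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sonomoment import evaluation_stats as ev


def naive_metrics(y, yhat):
    """Second implementation: textbook formulas in plain Python."""
    n = len(y)
    loss = sum((a - b) ** 2 for a, b in zip(y, yhat)) / n
    r = math.sqrt(loss)
    my = sum(y) / n
    mh = sum(yhat) / n
    cov = sum((a - my) * (b - mh) for a, b in zip(y, yhat))
    vy = sum((a - my) ** 2 for a in y)
    vh = sum((b - mh) ** 2 for b in yhat)
    r2 = cov * cov / (vy * vh)
    return loss, r, r2


class TestRegressionMetrics:
    def test_zero_residual_zero_loss(self):
        s = ev.EvalSeries(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert ev.regression_loss(s) == 0.0

    def test_hand_computed_example(self):
        s = ev.EvalSeries(np.array([100.0, 50.0]), np.array([90.0, 60.0]))
        assert ev.regression_loss(s) == pytest.approx(100.0)
        assert ev.rmse(s) == pytest.approx(10.0)

    def test_n_rmse_example(self):
        s = ev.EvalSeries(
            np.array([100.0, 50.0]), np.array([90.0, 60.0]), peak_moment=100.0
        )
        assert ev.n_rmse(s) == pytest.approx(0.10)

    def test_loss_equals_rmse_squared(self, rng):
        for _ in range(20):
            s = ev.EvalSeries(rng.standard_normal(50), rng.standard_normal(50))
            assert ev.regression_loss(s) == pytest.approx(ev.rmse(s) ** 2, rel=1e-12)

    def test_scaling_homogeneity(self, rng):
        y, yhat = rng.standard_normal(40) + 5, rng.standard_normal(40) + 5
        a = ev.EvalSeries(y, yhat, peak_moment=float(np.max(np.abs(y))))
        b = ev.EvalSeries(3 * y, 3 * yhat, peak_moment=float(np.max(np.abs(3 * y))))
        assert ev.rmse(b) == pytest.approx(3 * ev.rmse(a), rel=1e-12)
        assert ev.n_rmse(b) == pytest.approx(ev.n_rmse(a), rel=1e-12)

    def test_zero_peak_rejected(self):
        s = ev.EvalSeries(np.array([1.0, 2.0]), np.array([1.0, 2.0]), peak_moment=0.0)
        with pytest.raises(ZeroDivisionError):
            ev.n_rmse(s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.EvalSeries(np.zeros(3), np.zeros(4))


class TestRSquared:
    def test_perfect_affine_relation_gives_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ev.r_squared(ev.EvalSeries(y, 2 * y + 3)) == pytest.approx(1.0)

    def test_small_example_matches_naive_formula(self):
        y = [1.0, 2.0, 3.0, 4.0]
        yhat = [1.0, 2.0, 3.0, 5.0]
        _, _, r2_naive = naive_metrics(y, yhat)
        got = ev.r_squared(ev.EvalSeries(np.array(y), np.array(yhat)))
        assert got == pytest.approx(r2_naive, rel=1e-12)

    def test_affine_invariance(self, rng):
        y, yhat = rng.standard_normal(30), rng.standard_normal(30)
        a = ev.r_squared(ev.EvalSeries(y, yhat))
        b = ev.r_squared(ev.EvalSeries(2.0 * y - 1.0, 0.5 * yhat + 7.0))
        assert b == pytest.approx(a, rel=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.r_squared(ev.EvalSeries(np.ones(5), np.arange(5.0)))

    def test_residual_form_available(self, rng):
        y = rng.standard_normal(50)
        yhat = y + 0.1 * rng.standard_normal(50)
        res = ev.r_squared(ev.EvalSeries(y, yhat), form="residual")
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert res == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)


def test_all_metrics_match_independent_implementation_on_seeded_series():
    """1,000 seeded random series: loss, RMSE, N-RMSE, R^2 vs plain Python."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(5, 40))
        y = rng.standard_normal(n) * rng.uniform(0.5, 50)
        yhat = y + rng.standard_normal(n) * rng.uniform(0.01, 5)
        s = ev.EvalSeries(y, yhat)
        loss_n, rmse_n, r2_n = naive_metrics(y.tolist(), yhat.tolist())
        assert abs(ev.regression_loss(s) - loss_n) <= 1e-10 * max(loss_n, 1)
        assert abs(ev.rmse(s) - rmse_n) <= 1e-10 * max(rmse_n, 1)
        assert abs(ev.r_squared(s) - r2_n) <= 1e-10
        assert ev.n_rmse(s) == pytest.approx(
            rmse_n / np.max(np.abs(y)), rel=1e-10
        )


class TestLinearFit:
    def test_identity_fit_exact(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ev.linear_fit(ev.EvalSeries(y, y))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_identity_recovered_within_2se(self, rng):
        y = rng.uniform(0, 100, 500)
        yhat = y + rng.standard_normal(500) * 3.0
        fit = ev.linear_fit(ev.EvalSeries(y, yhat))
        assert abs(fit.slope - 1.0) < 2 * fit.slope_se
        assert abs(fit.intercept) < 2 * fit.intercept_se

    def test_matches_scipy_linregress(self, rng):
        y = rng.standard_normal(40)
        yhat = 0.9 * y + 0.3 + 0.1 * rng.standard_normal(40)
        fit = ev.linear_fit(ev.EvalSeries(y, yhat))
        ref = sps.linregress(y, yhat)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-10)
        assert fit.slope_se == pytest.approx(ref.stderr, rel=1e-10)
        assert fit.slope_p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_two_samples_rejected(self):
        with pytest.raises(ValueError):
            ev.linear_fit(ev.EvalSeries(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestCompareGroups:
    def test_identical_columns_nothing_significant(self, rng):
        col = rng.standard_normal(8)
        report = ev.compare_groups(np.stack([col, col, col], axis=1))
        assert report.omnibus_p > 0.05 or np.isnan(report.omnibus_p)
        assert report.significant_pairs() == []

    def test_large_shift_detected_by_paired_branch(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(8)
        b = a + 10.0 + 0.1 * rng.standard_normal(8)
        report = ev.compare_groups(np.stack([a, b], axis=1))
        assert report.branch == "parametric"
        assert report.omnibus_p < 0.05
        # oracle: paired t computed from the textbook formula
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        assert report.omnibus_p == pytest.approx(p, rel=1e-10)

    def test_heavy_tailed_column_selects_nonparametric(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(12)
        b = rng.standard_cauchy(12) * 100  # fails Shapiro-Wilk decisively
        report = ev.compare_groups(np.stack([a, b], axis=1))
        assert report.normality_p[1] < 0.05
        assert report.branch == "nonparametric"
        assert report.omnibus_name.startswith("Wilcoxon")

    def test_branch_is_pure_function_of_sw_pvalues(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = r.standard_normal((10, 3)) + r.standard_cauchy((10, 3)) * (
                seed % 2
            )
            report = ev.compare_groups(data)
            expected = (
                "parametric"
                if all(p >= 0.05 for p in report.normality_p)
                else "nonparametric"
            )
            assert report.branch == expected

    def test_three_conditions_parametric_omnibus(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(10)
        data = np.stack([base, base + 5, base + 10], axis=1)
        data += 0.2 * rng.standard_normal(data.shape)
        report = ev.compare_groups(data)
        assert report.branch == "parametric"
        assert report.omnibus_name.startswith("RM-ANOVA")
        assert report.omnibus_p < 0.001
        assert (0, 2) in report.significant_pairs()

    def test_three_conditions_friedman_branch(self):
        rng = np.random.default_rng(13)
        base = np.abs(rng.standard_cauchy(12)) * 50
        data = np.stack([base, base + 30, base + 60], axis=1)
        report = ev.compare_groups(data)
        assert report.branch == "nonparametric"
        fr = sps.friedmanchisquare(data[:, 0], data[:, 1], data[:, 2])
        assert report.omnibus_statistic == pytest.approx(fr.statistic, rel=1e-10)
        assert (0, 2) in report.significant_pairs()

    def test_significance_flags_follow_asterisk_convention(self):
        r = ev.PairwiseResult((0, 1), 0.0, 0.0004)
        assert r.flags == "***"
        assert ev.PairwiseResult((0, 1), 0.0, 0.02).flags == "*"
        assert ev.PairwiseResult((0, 1), 0.0, 0.2).flags == ""

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            ev.compare_groups(np.zeros((2, 3)))
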