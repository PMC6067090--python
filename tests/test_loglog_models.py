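"""Log-log model ladder: fits, closed-form scale, nested testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halleymort.halley_pool import AgeSchema, RatePoint, representative_age
from halleymort.loglog_models import (
    LogLogDataset,
    build_dataset,
    fit_inverse,
    fit_linear,
    fit_quadratic,
    nested_f_test,
    residual_diagnostics,
    sweep_upper_age,
)


def rates_from_curve(fn, schema=None, upper=95.0):
    schema = schema or AgeSchema.who_default()
    pts = []
    for iv in schema.intervals:
        if iv[1] <= upper:
            x = representative_age(iv)
            pts.append(RatePoint(x, fn(x), 1.0, iv))
    return pts


class TestBuildDataset:
    @pytest.mark.parametrize("upper, n", [(90, 25), (10, 9), (15, 10), (5, 8)])
    def test_bin_counts_by_window(self, upper, n):
        rates = rates_from_curve(lambda x: 100.0 / x)
        assert build_dataset(rates, upper).n == n

    def test_zero_rate_bins_excluded(self):
        rates = rates_from_curve(lambda x: 100.0 / x)
        rates[5] = RatePoint(rates[5].x, 0.0, 0.0, rates[5].interval)
        assert build_dataset(rates, 90).n == 24

    def test_too_few_points_is_an_error(self):
        rates = rates_from_curve(lambda x: 100.0 / x)[:2]
        with pytest.raises(ValueError, match="3"):
            build_dataset(rates, 1 / 28)


class TestFitQuadratic:
    def test_exact_inverse_data_has_zero_curvature(self):
        data = build_dataset(rates_from_curve(lambda x: np.exp(3.0) / x), 90)
        fit = fit_quadratic(data)
        assert fit.delta == pytest.approx(0.0, abs=1e-8)
        assert fit.gamma == pytest.approx(-1.0, abs=1e-8)
        assert fit.constant == pytest.approx(3.0, abs=1e-7)

    def test_recovers_planted_coefficients(self):
        fn = lambda x: np.exp(1.0 - 2.0 * np.log(x) + 0.5 * np.log(x) ** 2)
        fit = fit_quadratic(build_dataset(rates_from_curve(fn), 90))
        assert (fit.constant, fit.gamma, fit.delta) == pytest.approx((1.0, -2.0, 0.5), abs=1e-7)

    def test_collinear_design_rejected(self):
        data = LogLogDataset(np.ones(5), np.arange(5.0), 90)
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(data)


class TestFitLinear:
    def test_exact_power_law(self):
        fit = fit_linear(build_dataset(rates_from_curve(lambda x: 50.0 * x**-0.7), 90))
        assert fit.gamma == pytest.approx(-0.7, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_three_point_hand_ols(self):
        # ln-pairs (0,2),(1,1),(2,0): perfect slope -1, intercept 2
        data = LogLogDataset(np.array([0.0, 1.0, 2.0]), np.array([2.0, 1.0, 0.0]), 90)
        fit = fit_linear(data)
        assert fit.gamma == pytest.approx(-1.0)
        assert fit.constant == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.gamma_vs_minus1.pvalue == pytest.approx(1.0)

    def test_adjusted_r2_below_r2_and_ci_contains_estimate(self):
        rng = np.random.default_rng(5)
        lnx = np.log(np.linspace(1, 20, 12))
        data = LogLogDataset(lnx, 3 - lnx + rng.normal(0, 0.2, 12), 90)
        fit = fit_linear(data)
        assert fit.r2_adj <= fit.r2
        assert fit.gamma_ci[0] <= fit.gamma <= fit.gamma_ci[1]

    def test_ci_coverage_near_nominal(self):
        """95% CI for the slope covers the true -1 at ~nominal rate."""
        rng = np.random.default_rng(11)
        lnx = np.log(AgeSchema.who_default().midpoints()[:9])
        hits = 0
        B = 400
        for _ in range(B):
            y = 2.0 - lnx + rng.normal(0, 0.3, len(lnx))
            fit = fit_linear(LogLogDataset(lnx, y, 10))
            hits += fit.gamma_ci[0] <= -1.0 <= fit.gamma_ci[1]
        assert 0.91 <= hits / B <= 0.985

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(LogLogDataset(np.zeros(4), np.arange(4.0), 90))


class TestFitInverse:
    def test_exact_inverse_scale_and_rb2(self):
        lnx = np.log(np.array([1.0, 2.0, 4.0]))
        data = LogLogDataset(lnx, np.log(2.0) - lnx, 90)
        fit = fit_inverse(data)
        assert fit.ln_mu1 == pytest.approx(np.log(2.0))
        assert fit.rb2 == pytest.approx(1.0)

    def test_two_point_hand_value(self):
        data = LogLogDataset(np.array([0.0, 1.0]), np.array([1.0, 0.0]), 90)
        fit = fit_inverse(data)
        assert fit.ln_mu1 == pytest.approx(1.0)
        assert fit.mu1 == pytest.approx(np.e)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equals_slope_fixed_intercept_oracle(self, seed):
        """The closed form is the argmin of sum(lnmu - (c - lnx))^2 over c."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        lnx = rng.normal(0, 2, n)
        lnmu = rng.normal(0, 3, n)
        fit = fit_inverse(LogLogDataset(lnx, lnmu, 90))
        # oracle: OLS of (lnmu + lnx) on a constant
        c_oracle = np.linalg.lstsq(np.ones((n, 1)), lnmu + lnx, rcond=None)[0][0]
        assert fit.ln_mu1 == pytest.approx(c_oracle, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rb2_never_exceeds_linear_r2(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 20)
        lnx = np.sort(rng.normal(0, 1.5, n))
        if np.ptp(lnx) == 0:
            lnx = lnx + np.arange(n) * 0.1
        lnmu = rng.normal(0, 2, n)
        data = LogLogDataset(lnx, lnmu, 90)
        assert fit_inverse(data).rb2 <= fit_linear(data).r2 + 1e-12


class TestNestedFTest:
    def test_equal_rss_gives_p_one(self):
        res = nested_f_test(1.0, 1.0, n=10, k_full=2, q=1)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_f_value(self):
        res = nested_f_test(2.0, 1.0, n=10, k_full=2, q=1)
        assert res.statistic == pytest.approx(8.0)
        assert res.pvalue == pytest.approx(0.0222, abs=2e-4)

    def test_perfect_full_fit_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            res = nested_f_test(1.0, 0.0, n=10, k_full=2, q=1)
        assert res.pvalue == 0.0

    def test_restricted_below_full_rejected(self):
        with pytest.raises(ValueError):
            nested_f_test(0.5, 1.0, n=10, k_full=2, q=1)

    def test_statistic_invariant_under_noise_rescaling(self):
        rng = np.random.default_rng(3)
        lnx = np.log(np.linspace(1, 30, 15))
        noise = rng.normal(0, 1, 15)
        stats = []
        for s in (0.1, 10.0):
            data = LogLogDataset(lnx, 2 - lnx + s * noise, 90)
            lin, inv = fit_linear(data), fit_inverse(data)
            stats.append(nested_f_test(inv.rss, lin.rss, 15, 2, 1).statistic)
        assert stats[0] == pytest.approx(stats[1], rel=1e-9)


class TestResidualDiagnostics:
    def test_zero_residuals_show_no_trend(self):
        data = build_dataset(rates_from_curve(lambda x: 10.0 / x), 90)
        trend, ushape = residual_diagnostics(fit_inverse(data))
        assert trend.pvalue > 0.99 and ushape.pvalue > 0.99

    def test_planted_quadratic_pattern_detected(self):
        lnx = np.log(np.linspace(1, 30, 15))
        rng = np.random.default_rng(9)
        lnmu = 2 - lnx + 0.15 * lnx**2 + rng.normal(0, 0.01, 15)
        fit = fit_linear(LogLogDataset(lnx, lnmu, 90))
        _, ushape = residual_diagnostics(fit)
        assert ushape.reject

    def test_ushape_skipped_below_four_points(self):
        data = LogLogDataset(np.array([0.0, 1.0, 2.0]), np.array([2.0, 1.1, 0.0]), 90)
        _, ushape = residual_diagnostics(fit_linear(data))
        assert ushape is None


class TestSweep:
    def test_exact_inverse_data_every_row_perfect(self):
        rates = rates_from_curve(lambda x: 1000.0 / x)
        table = sweep_upper_age(rates)
        assert len(table) == 18
        assert table.gamma.to_numpy() == pytest.approx(np.full(18, -1.0))
        assert table.r2.to_numpy() == pytest.approx(np.ones(18))
        assert table.rb2.to_numpy() == pytest.approx(np.ones(18))

    def test_row_n_matches_window(self):
        rates = rates_from_curve(lambda x: 1000.0 / x)
        table = sweep_upper_age(rates).set_index("upper_age")
        assert table.loc[10, "n"] == 9
        assert table.loc[90, "n"] == 25
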