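"""Weighted surrogacy regression, R² interval, prediction band and STE."""

import math

import numpy as np
import pytest
from scipy import stats

from seetrial import (
    SurrogacyError,
    fit_weighted_regression,
    plot_surrogacy,
    prediction_interval,
    r2_bootstrap_interval,
    r2_confidence_interval,
    surrogate_threshold,
)
from conftest import effects_frame, wls_oracle


def random_effects(rng, n=8):
    x = rng.normal(-0.1, 0.4, n)
    y = 0.8 * x + rng.normal(0, 0.2, n)
    w = rng.integers(50, 2000, n).astype(float)
    return effects_frame(x, y, w)


class TestWeightedRegression:
    def test_three_point_closed_form(self):
        eff = effects_frame([-0.2, 0.0, 0.2], [-0.1, 0.1, 0.0], [1, 1, 1])
        fit = fit_weighted_regression(eff)
        assert fit.slope == pytest.approx(0.25)
        assert fit.r2 == pytest.approx(0.25)
        assert fit.r2_ci is None  # interval needs >= 4 groups

    def test_collinear_points_give_r2_one(self):
        x = np.array([-0.4, -0.2, 0.1, 0.3])
        eff = effects_frame(x, 0.6 * x - 0.02, [1, 2, 3, 4])
        fit = fit_weighted_regression(eff)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-16)

    def test_weight_replication_equivalence(self):
        x = [-0.3, -0.1, 0.1, 0.2]
        y = [-0.25, 0.0, 0.05, 0.2]
        weighted = fit_weighted_regression(effects_frame(x, y, [1, 2, 2, 1]))
        x_rep = [x[0], x[1], x[1], x[2], x[2], x[3]]
        y_rep = [y[0], y[1], y[1], y[2], y[2], y[3]]
        replicated = fit_weighted_regression(
            effects_frame(x_rep, y_rep, [1] * 6))
        assert replicated.slope == pytest.approx(weighted.slope, abs=1e-12)
        assert replicated.r2 == pytest.approx(weighted.r2, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        eff = random_effects(rng)
        fit = fit_weighted_regression(eff)
        b0, b1, sigma2, r2, xtwx_inv = wls_oracle(
            eff["log_hr_surrogate"], eff["log_hr_true"], eff["n_subjects"])
        assert fit.intercept == pytest.approx(b0, abs=1e-8)
        assert fit.slope == pytest.approx(b1, abs=1e-8)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-8)
        np.testing.assert_allclose(fit.xtwx_inv, xtwx_inv, atol=1e-10)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_r2_equals_squared_weighted_pearson(self, seed):
        rng = np.random.default_rng(seed)
        eff = random_effects(rng)
        fit = fit_weighted_regression(eff)
        x = eff["log_hr_surrogate"].to_numpy()
        y = eff["log_hr_true"].to_numpy()
        w = eff["n_subjects"].to_numpy()
        xb, yb = np.average(x, weights=w), np.average(y, weights=w)
        cov = np.average((x - xb) * (y - yb), weights=w)
        corr = cov / math.sqrt(
            np.average((x - xb) ** 2, weights=w)
            * np.average((y - yb) ** 2, weights=w))
        assert fit.r2 == pytest.approx(corr**2, abs=1e-10)

    def test_common_hr_factor_changes_only_intercept(self):
        rng = np.random.default_rng(6)
        eff = random_effects(rng)
        fit = fit_weighted_regression(eff)
        shifted = eff.assign(
            log_hr_true=eff["log_hr_true"] + math.log(1.3))
        fit2 = fit_weighted_regression(shifted)
        assert fit2.slope == pytest.approx(fit.slope, abs=1e-10)
        assert fit2.r2 == pytest.approx(fit.r2, abs=1e-10)
        assert fit2.intercept == pytest.approx(
            fit.intercept + math.log(1.3), abs=1e-10)
        lo, hi = prediction_interval(fit, 0.0)
        lo2, hi2 = prediction_interval(fit2, 0.0)
        assert (hi2 - lo2) == pytest.approx(hi - lo, abs=1e-10)

    def test_unusable_groups_excluded(self):
        eff = effects_frame([-0.3, -0.1, 0.1, 0.2, 0.5],
                            [-0.2, 0.0, 0.1, 0.1, 9.9],
                            [100, 100, 100, 100, 100],
                            usable=[True, True, True, True, False])
        fit = fit_weighted_regression(eff)
        assert fit.n_groups == 4

    def test_too_few_groups_rejected(self):
        with pytest.raises(SurrogacyError, match="at least 3"):
            fit_weighted_regression(effects_frame([0.1, 0.2], [0.0, 0.1],
                                                  [1, 1]))

    def test_identical_x_rejected(self):
        with pytest.raises(SurrogacyError, match="slope is undefined"):
            fit_weighted_regression(
                effects_frame([0.1] * 4, [0.0, 0.1, 0.2, 0.3], [1] * 4))

    def test_identical_y_warns_r2_zero(self):
        eff = effects_frame([-0.2, 0.0, 0.2, 0.4], [0.1] * 4, [1] * 4)
        with pytest.warns(UserWarning, match="R² set to 0"):
            fit = fit_weighted_regression(eff)
        assert fit.r2 == 0.0


class TestR2Interval:
    @pytest.mark.parametrize("r2, n, expected", [
        (0.85, 9, (0.63, 1.00)),
        (0.23, 14, (0.00, 0.67)),
        (0.23, 17, (0.00, 0.62)),
        (0.29, 11, (0.00, 0.82)),
    ])
    def test_delta_method_reproduces_published_intervals(self, r2, n,
                                                         expected):
        lo, hi = r2_confidence_interval(r2, n)
        assert round(lo, 2) == expected[0]
        assert round(hi, 2) == expected[1]

    def test_boundary_r2_one_collapses(self):
        assert r2_confidence_interval(1.0, 9) == (1.0, 1.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(SurrogacyError):
            r2_confidence_interval(0.5, 3)

    def test_bootstrap_interval_seeded_and_ordered(self):
        rng = np.random.default_rng(7)
        eff = random_effects(rng, n=10)
        lo, hi = r2_bootstrap_interval(eff, n_boot=200, seed=42)
        lo2, hi2 = r2_bootstrap_interval(eff, n_boot=200, seed=42)
        assert (lo, hi) == (lo2, hi2)
        assert 0.0 <= lo <= hi <= 1.0


class TestPredictionInterval:
    def test_zero_residual_variance_collapses_to_line(self):
        x = np.array([-0.4, -0.2, 0.1, 0.3])
        fit = fit_weighted_regression(effects_frame(x, 0.8 * x, [1] * 4))
        lo, hi = prediction_interval(fit, -0.1)
        assert lo == pytest.approx(fit.predict(-0.1), abs=1e-12)
        assert hi == pytest.approx(fit.predict(-0.1), abs=1e-12)

    def test_narrowest_at_weighted_mean(self):
        rng = np.random.default_rng(8)
        eff = random_effects(rng)
        fit = fit_weighted_regression(eff)
        xbar = np.average(fit.x, weights=fit.w)
        grid = np.linspace(fit.x.min() - 0.5, fit.x.max() + 0.5, 101)
        grid = np.sort(np.append(grid, xbar))
        lo, hi = prediction_interval(fit, grid)
        widths = hi - lo
        assert grid[np.argmin(widths)] == pytest.approx(xbar)

    def test_matrix_algebra_oracle_at_zero(self):
        x = [-0.35, -0.15, 0.05, 0.25]
        y = [-0.30, -0.05, 0.00, 0.18]
        w = [3.0, 1.0, 2.0, 2.0]
        fit = fit_weighted_regression(effects_frame(x, y, w))
        b0, b1, sigma2, _, xtwx_inv = wls_oracle(x, y, w)
        x0 = np.array([1.0, 0.0])
        w0 = np.mean(w)
        half = stats.t.ppf(0.975, df=2) * math.sqrt(
            sigma2 * (1.0 / w0 + x0 @ xtwx_inv @ x0))
        lo, hi = prediction_interval(fit, 0.0)
        assert lo == pytest.approx(b0 - half, abs=1e-10)
        assert hi == pytest.approx(b0 + half, abs=1e-10)


class TestSurrogateThreshold:
    def test_line_crossing_with_zero_variance(self):
        x = np.array([-0.5, -0.3, -0.1, 0.1])
        fit = fit_weighted_regression(effects_frame(x, x + 0.05, [1] * 4))
        ste = surrogate_threshold(fit)
        assert ste.hr == pytest.approx(math.exp(-0.05), abs=1e-9)
        assert ste.reason is None

    def test_huge_variance_gives_absent(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.3, 6)
        y = x + rng.normal(0, 3.0, 6)  # swamps the signal
        fit = fit_weighted_regression(effects_frame(x, y, [1] * 6))
        ste = surrogate_threshold(fit)
        if fit.slope <= 0:
            assert "slope" in ste.reason
        else:
            assert ste.hr is None
            assert "too wide" in ste.reason

    def test_negative_slope_gives_reasoned_absence(self):
        x = np.array([-0.4, -0.2, 0.0, 0.2])
        fit = fit_weighted_regression(effects_frame(x, -0.5 * x, [1] * 4))
        ste = surrogate_threshold(fit)
        assert ste.hr is None
        assert "slope" in ste.reason

    def test_bisection_matches_grid_scan(self, small_trial):
        from seetrial import run_pipeline
        fit = run_pipeline(small_trial, min_events=30).fit
        ste = surrogate_threshold(fit)
        assert ste.hr is not None
        grid = np.arange(math.log(0.05), 0.0, 1e-6)
        upper = prediction_interval(fit, grid)[1]
        crossing = grid[int(np.argmax(upper >= 0.0))]
        assert math.log(ste.hr) == pytest.approx(crossing, abs=2e-6)

    def test_ste_plugged_back_gives_zero_upper_limit(self, small_trial):
        from seetrial import run_pipeline
        fit = run_pipeline(small_trial, min_events=30).fit
        ste = surrogate_threshold(fit)
        _, hi = prediction_interval(fit, math.log(ste.hr))
        assert abs(hi) < 1e-6


def test_plot_writes_figure(tmp_path, small_trial):
    from seetrial import run_pipeline
    fit = run_pipeline(small_trial, min_events=30).fit
    out = tmp_path / "fit.png"
    plot_surrogacy(fit, out)
    assert out.stat().st_size > 0
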