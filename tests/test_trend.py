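import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infotrend import (
    build_basis,
    fit_trend,
    instantaneous_derivatives,
    compute_mid,
    bootstrap_mid,
    falsification_contrast,
)
from conftest import make_series
from oracles import normal_equations


class TestBasis:
    def test_partition_of_unity(self, linear_series):
        basis = build_basis(linear_series.dates, df=4)
        full = basis.full_design(linear_series.time_years)
        assert full.shape == (36, 5)
        assert np.allclose(full.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((full >= 0) & (full <= 1))

    def test_df4_cubic_has_one_interior_knot_at_median(self, linear_series):
        basis = build_basis(linear_series.dates, df=4, degree=3)
        interior = basis.knots[basis.degree + 1:-(basis.degree + 1)]
        assert len(interior) == 1  # df - degree
        assert interior[0] == pytest.approx(np.median(linear_series.time_years))

    @pytest.mark.parametrize("df,degree,n_interior", [(3, 3, 0), (5, 3, 2),
                                                      (4, 2, 2)])
    def test_interior_knot_count_is_df_minus_degree(self, linear_series,
                                                    df, degree, n_interior):
        basis = build_basis(linear_series.dates, df=df, degree=degree)
        assert len(basis.knots) - 2 * (degree + 1) == n_interior
        assert basis.design(linear_series.time_years).shape[1] == df

    def test_evaluation_outside_boundary_raises(self, linear_series):
        basis = build_basis(linear_series.dates)
        with pytest.raises(ValueError, match="outside boundary"):
            basis.design(np.array([linear_series.time_years[-1] + 1.0]))

    def test_too_few_points_raises_with_minimum(self):
        short = make_series(np.arange(5.0))
        with pytest.raises(ValueError, match="df \\+ 1"):
            build_basis(short.dates, df=4)


class TestFit:
    def test_linear_series_reproduced_exactly(self, linear_series):
        fit = fit_trend(linear_series)
        assert np.allclose(fit.fitted, linear_series.values, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(12, 80))
            s = make_series(rng.normal(50, 10, n))
            fit = fit_trend(s)
            X = np.column_stack([np.ones(n),
                                 fit.basis.design(s.time_years)])
            expected = normal_equations(X, s.values)
            assert np.allclose(fit.coef, expected, atol=1e-6)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.normal(50, 10, 40))
        fit = fit_trend(s)
        X = np.column_stack([np.ones(40), fit.basis.design(s.time_years)])
        assert np.allclose(X.T @ fit.residuals, 0.0, atol=1e-8)

    def test_constant_series_flags_r2_undefined(self):
        fit = fit_trend(make_series(np.full(30, 7.0)))
        assert not fit.r2_defined
        assert np.allclose(instantaneous_derivatives(fit), 0.0, atol=1e-8)

    def test_adjusted_r2_below_r2_for_noisy_data(self):
        rng = np.random.default_rng(5)
        fit = fit_trend(make_series(50 + rng.normal(0, 5, 40)))
        assert fit.adj_r_squared < fit.r_squared <= 1.0

    def test_missing_values_rejected(self):
        v = np.arange(30.0)
        v[4] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_trend(make_series(v))


class TestDerivativesAndMid:
    def test_linear_series_constant_derivative(self, linear_series):
        # 0.5 per month = 6 per year on the numeric-year axis
        fit = fit_trend(linear_series)
        deriv = instantaneous_derivatives(fit)
        assert np.allclose(deriv, 6.0, atol=1e-8)
        assert compute_mid(fit) == pytest.approx(0.5, abs=1e-8)

    def test_derivative_matches_central_difference(self):
        rng = np.random.default_rng(3)
        s = make_series(50 + np.cumsum(rng.normal(0, 2, 48)))
        fit = fit_trend(s)
        deriv = instantaneous_derivatives(fit)
        t, h = s.time_years, 1e-5
        for i in range(1, len(s) - 1):  # interior months stay inside the domain
            numeric = (fit.predict(np.array([t[i] + h]))
                       - fit.predict(np.array([t[i] - h]))) / (2 * h)
            assert deriv[i] == pytest.approx(numeric.item(), abs=1e-4)

    def test_time_reversal_negates_mid(self):
        rng = np.random.default_rng(9)
        values = 40 + np.cumsum(rng.normal(0.4, 2, 50))
        mid_fwd = compute_mid(fit_trend(make_series(values)))
        mid_rev = compute_mid(fit_trend(make_series(values[::-1])))
        assert mid_rev == pytest.approx(-mid_fwd, abs=1e-8)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0,
                           allow_nan=False, allow_infinity=False))
    def test_positive_scaling_scales_mid(self, scale):
        rng = np.random.default_rng(7)
        values = 30 + np.cumsum(rng.normal(0.3, 1.5, 40))
        base = compute_mid(fit_trend(make_series(values)))
        scaled = compute_mid(fit_trend(make_series(values * scale)))
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestBootstrap:
    def test_noiseless_series_collapses_to_point(self, linear_series):
        est = bootstrap_mid(linear_series, n_boot=200, seed=1)
        assert np.allclose(est.boot_mids, est.mid, atol=1e-10)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-10)
        assert est.p_value == pytest.approx(2.0 / 201)

    def test_same_seed_reproduces_estimate(self):
        rng = np.random.default_rng(2)
        s = make_series(40 + 0.4 * np.arange(48) + rng.normal(0, 4, 48))
        a = bootstrap_mid(s, n_boot=300, seed=5)
        b = bootstrap_mid(s, n_boot=300, seed=5)
        assert a.mid == b.mid and a.p_value == b.p_value
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_bounds_ordered_and_mid_from_derivatives(self):
        rng = np.random.default_rng(8)
        s = make_series(40 + rng.normal(0, 5, 40))
        est = bootstrap_mid(s, n_boot=300, seed=3)
        assert est.ci_low <= est.ci_high
        assert est.mid == pytest.approx(est.derivatives.mean() / 12.0, abs=0)

    def test_tiny_n_boot_rejected_and_small_warned(self, linear_series, caplog):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_mid(linear_series, n_boot=1, seed=0)
        with caplog.at_level(logging.WARNING):
            bootstrap_mid(linear_series, n_boot=50, seed=0)
        assert any("n_boot" in r.message for r in caplog.records)

    def test_leverage_adjustment_widens_interval(self):
        rng = np.random.default_rng(4)
        s = make_series(40 + rng.normal(0, 5, 40))
        raw = bootstrap_mid(s, n_boot=500, seed=6)
        adj = bootstrap_mid(s, n_boot=500, seed=6, leverage_adjust=True)
        assert (adj.ci_high - adj.ci_low) > (raw.ci_high - raw.ci_low)


class TestFalsificationContrast:
    def _est(self, p, **kw):
        defaults = dict(mid=0.4, derivatives=np.zeros(3), ci_low=0.1,
                        ci_high=0.6, p_value=p, n_boot=1000, seed=0, df=4,
                        degree=3, adj_r_squared=0.6, r2_defined=True)
        defaults.update(kw)
        from infotrend import TrendEstimate
        return TrendEstimate(**defaults)

    @pytest.mark.parametrize("p_target,p_control,verdict", [
        (0.001, 0.40, "trend specific to target"),
        (0.30, 0.40, "no specific trend"),
        (0.001, 0.01, "nonspecific rise; confounding not excluded"),
        (0.30, 0.01, "control trend only; target shows no trend"),
    ])
    def test_verdicts(self, p_target, p_control, verdict):
        report = falsification_contrast(self._est(p_target),
                                        self._est(p_control))
        assert report["verdict"] == verdict

    def test_mismatched_settings_invalid(self):
        with pytest.raises(ValueError, match="spline settings"):
            falsification_contrast(self._est(0.01), self._est(0.5, df=5))
        with pytest.raises(ValueError, match="iteration counts"):
            falsification_contrast(self._est(0.01),
                                   self._est(0.5, n_boot=500))
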