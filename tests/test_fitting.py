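"""Parameter estimation: round trips, closed forms, statistics and ranking."""

import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from rehydkin import (
    DegenerateCurveError,
    FitStats,
    ModelFit,
    PelegParams,
    ProposedParams,
    RehydrationCurve,
    WeibullParams,
    fit_peleg,
    fit_proposed,
    fit_weibull,
    goodness_of_fit,
    peleg_moisture,
    proposed_moisture,
    rank_models,
    weibull_moisture,
)


class TestFitPeleg:
    def test_noise_free_round_trip(self, peleg_curve):
        curve, true = peleg_curve
        fit = fit_peleg(curve)
        assert fit.converged
        assert fit.params.k1 == pytest.approx(true.k1, rel=1e-6)
        assert fit.params.k2 == pytest.approx(true.k2, rel=1e-6)
        assert fit.stats.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.stats.RMSE == pytest.approx(0.0, abs=1e-10)
        assert fit.stats.chi2 == pytest.approx(0.0, abs=1e-10)
        assert fit.Xeq_derived == pytest.approx(0.10 + 1 / true.k2, rel=1e-6)

    def test_constant_curve_is_degenerate(self, time_grid):
        curve = RehydrationCurve("control", 55.0, time_grid,
                                 np.full_like(time_grid, 0.4), 0.4)
        with pytest.raises(DegenerateCurveError):
            fit_peleg(curve)

    def test_equilibrium_decreases_with_capacity_constant(self, time_grid):
        """Higher fitted k2 means lower derived equilibrium at fixed Xw0."""
        fits = []
        for k2 in (0.15, 0.20, 0.30):
            x = peleg_moisture(time_grid, 0.1, PelegParams(6.0, k2))
            fits.append(fit_peleg(RehydrationCurve("c", 55, time_grid, x, 0.1)))
        xeqs = [f.Xeq_derived for f in fits]
        assert xeqs == sorted(xeqs, reverse=True)


class TestFitWeibull:
    def test_noise_free_round_trip(self, time_grid):
        true = WeibullParams(0.78, 23.18, 3.1)
        x = weibull_moisture(time_grid, 0.1, true)
        fit = fit_weibull(RehydrationCurve("MB", 55, time_grid, x, 0.1))
        assert fit.converged
        assert fit.params.alpha == pytest.approx(true.alpha, rel=1e-5)
        assert fit.params.beta == pytest.approx(true.beta, rel=1e-5)
        assert fit.params.Xeq == pytest.approx(true.Xeq, rel=1e-5)

    def test_bounds_respected_on_noisy_fits(self, time_grid):
        rng = np.random.default_rng(5)
        for _ in range(10):
            true = WeibullParams(rng.uniform(0.6, 0.93), rng.uniform(10, 55),
                                 rng.uniform(3.0, 6.9))
            x = np.maximum(weibull_moisture(time_grid, 0.1, true)
                           + rng.normal(0, 0.05, len(time_grid)), 0)
            fit = fit_weibull(RehydrationCurve("c", 55, time_grid, x, float(x[0])))
            assert 0 < fit.params.alpha <= 5.0
            assert fit.params.beta > 0

    def test_refinement_never_worse_than_initialization(self, time_grid):
        rng = np.random.default_rng(11)
        x = np.maximum(weibull_moisture(time_grid, 0.1, WeibullParams(0.8, 25, 4.0))
                       + rng.normal(0, 0.05, len(time_grid)), 0)
        curve = RehydrationCurve("c", 55, time_grid, x, float(x[0]))
        fit = fit_weibull(curve)
        # rebuild the documented initialization point
        xeq0 = x.max() * 1.05
        target = curve.Xw0 + (1 - math.exp(-1)) * (xeq0 - curve.Xw0)
        beta0 = time_grid[time_grid > 0][
            np.argmin(np.abs(x[time_grid > 0] - target))
        ]
        sse_init = np.sum(
            (weibull_moisture(time_grid, curve.Xw0, WeibullParams(1.0, beta0, xeq0)) - x) ** 2
        )
        sse_fit = np.sum(
            (weibull_moisture(time_grid, curve.Xw0, fit.params) - x) ** 2
        )
        assert sse_fit <= sse_init + 1e-12


class TestFitProposed:
    def test_noise_free_round_trip_is_exact(self):
        t = np.arange(5.0, 61, 5)
        true = ProposedParams(k=0.06, Xeq=-1.5)
        x = proposed_moisture(t, 0.1, true)
        fit = fit_proposed(RehydrationCurve("c", 55, t, x, 0.1,
                                            allow_negative_moisture=True))
        assert fit.params.k == pytest.approx(true.k, rel=1e-10)
        assert fit.params.Xeq == pytest.approx(true.Xeq, rel=1e-10)

    def test_closed_form_agrees_with_nonlinear_least_squares(self):
        """The problem is linear after reparameterisation, so NLS started at the
        closed form must stay there."""
        rng = np.random.default_rng(3)
        t = np.arange(5.0, 61, 5)
        x = proposed_moisture(t, 0.1, ProposedParams(0.06, -1.5)) + rng.normal(0, 0.05, len(t))
        fit = fit_proposed(RehydrationCurve("c", 55, t, x, 0.1,
                                            allow_negative_moisture=True))

        def resid(p):
            return proposed_moisture(t, 0.1, ProposedParams(math.exp(p[0]), p[1])) - x

        res = least_squares(resid, [math.log(fit.params.k), fit.params.Xeq],
                            ftol=1e-14, xtol=1e-14, gtol=1e-14)
        assert math.exp(res.x[0]) == pytest.approx(fit.params.k, rel=1e-8)
        assert res.x[1] == pytest.approx(fit.params.Xeq, abs=1e-8)

    def test_flat_curve_is_degenerate(self):
        t = np.arange(5.0, 61, 5)
        curve = RehydrationCurve("c", 55, t, np.full_like(t, 0.5), 0.5)
        with pytest.raises(DegenerateCurveError):
            fit_proposed(curve)

    def test_underdetermined_curve_rejected(self):
        with pytest.raises(ValueError):
            RehydrationCurve("c", 55, np.array([5.0, 10.0]), np.array([0.5, 0.8]), 0.1)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        obs = np.array([0.1, 0.5, 1.2, 2.0])
        s = goodness_of_fit(obs, obs, Z=2)
        assert (s.R2, s.RMSE, s.chi2) == (1.0, 0.0, 0.0)

    def test_hand_computed_residuals(self):
        obs = np.array([1.1, 1.9, 3.2])
        pred = np.array([1.0, 2.0, 3.0])  # residuals 0.1, -0.1, 0.2
        s = goodness_of_fit(obs, pred, Z=1)
        assert s.RMSE == pytest.approx(math.sqrt(0.06 / 3), rel=1e-12)
        assert s.chi2 == pytest.approx(0.03, rel=1e-12)

    def test_residual_scaling_law(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred1 = obs + np.array([0.1, -0.2, 0.05, 0.15])
        pred2 = obs + 2 * np.array([0.1, -0.2, 0.05, 0.15])
        s1 = goodness_of_fit(obs, pred1, Z=1)
        s2 = goodness_of_fit(obs, pred2, Z=1)
        assert s2.chi2 == pytest.approx(4 * s1.chi2, rel=1e-12)
        assert s2.RMSE == pytest.approx(2 * s1.RMSE, rel=1e-12)

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0, 2.0], Z=2)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 1.1, 0.9], Z=1)

    def test_chi2_rmse_identity(self, time_grid):
        """chi2*(N-Z) == RMSE^2 * N, the algebraic link between the two statistics."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = np.maximum(
                peleg_moisture(time_grid, 0.1, PelegParams(7.0, 0.2))
                + rng.normal(0, 0.05, len(time_grid)), 0)
            for fit in (fit_peleg, fit_weibull):
                f = fit(RehydrationCurve("c", 55, time_grid, x, float(x[0])))
                s = f.stats
                assert s.chi2 * (s.N - s.Z) == pytest.approx(s.RMSE**2 * s.N, rel=1e-12)


def _fit(r2, rmse, chi2, z, name="m"):
    return ModelFit(name, None, None, FitStats(r2, rmse, chi2, 13, z), True)


class TestRankModels:
    def test_orders_by_r2_then_rmse(self):
        fits = [_fit(0.98, 0.09, 0.01, 2, "a"),
                _fit(0.994, 0.064, 0.005, 2, "b"),
                _fit(0.994, 0.07, 0.005, 3, "c")]
        ranked = rank_models(fits)
        assert [f.model for f in ranked] == ["b", "c", "a"]

    def test_single_fit_unchanged(self):
        fits = [_fit(0.9, 0.1, 0.01, 2)]
        assert rank_models(fits) == fits

    def test_ties_broken_by_parameter_count_then_input_order(self):
        fits = [_fit(0.99, 0.05, 0.004, 3, "first"),
                _fit(0.99, 0.05, 0.004, 2, "second"),
                _fit(0.99, 0.05, 0.004, 3, "third")]
        assert [f.model for f in rank_models(fits)] == ["second", "first", "third"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


def test_moisture_ratio_statistics_differ_but_parameters_match(peleg_curve, time_grid):
    """Switching the residual variable rescales the statistics, not the estimates."""
    curve, _ = peleg_curve
    rng = np.random.default_rng(9)
    x = np.maximum(curve.moistures + rng.normal(0, 0.05, len(time_grid)), 0)
    noisy = RehydrationCurve("control", 55.0, time_grid, x, float(x[0]))
    fm = fit_peleg(noisy, residual_on="moisture")
    fr = fit_peleg(noisy, residual_on="moisture_ratio")
    assert fm.params.k1 == pytest.approx(fr.params.k1, rel=1e-12)
    assert fm.stats.RMSE != pytest.approx(fr.stats.RMSE, rel=1e-3)
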