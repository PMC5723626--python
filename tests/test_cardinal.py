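"""Cardinal temperature extraction and consensus estimates."""

import math

import numpy as np
import pytest

import tpcfit as tp
from tpcfit.cardinal import (cardinal_estimates, consensus, ct_limits,
                             default_window, shape_stats, t50_limits, t_opt)
from tpcfit.fitting import akaike_weights, fit_model


def _fit_from_params(mid, params, lo, hi, n=30):
    """A converged FitResult whose parameters equal ``params`` exactly
    (fit to its own noiseless predictions)."""
    T = np.linspace(lo, hi, n)
    rates = tp.evaluate(mid, params, T)
    curve = tp.PreparedCurve(f"m{mid}", T, rates)
    fit = fit_model(mid, curve, start=dict(params))
    assert fit.converged and fit.rss < 1e-10
    return fit


class TestTopt:
    def test_gaussian_peak_at_reference(self, gaussian_fit):
        topt, rmax, flags = t_opt(gaussian_fit)
        assert topt == pytest.approx(20.0, abs=1e-4)
        assert rmax == pytest.approx(1.0, abs=1e-6)
        assert not flags

    def test_quadratic_vertex_closed_form(self):
        fit = _fit_from_params(11, {"a": -3.0, "b": 4.0, "c": -1.0},
                               1.05, 2.95, n=12)
        topt, rmax, _ = t_opt(fit)
        assert topt == pytest.approx(2.0, abs=1e-4)   # -b/(2c)
        assert rmax == pytest.approx(1.0, abs=1e-6)

    def test_sine_peak_matches_dense_grid(self):
        params = {"r_max": 0.9, "t_min": 2.0, "t_max": 30.0,
                  "a": 1.3, "b": 0.8}
        fit = _fit_from_params(15, params, 4.0, 28.0)
        topt, _, _ = t_opt(fit)
        grid = np.arange(2.0, 30.0, 0.001)
        brute = grid[np.argmax(tp.evaluate(15, params, grid))]
        assert topt == pytest.approx(brute, abs=0.01)

    def test_boundary_optimum_is_flagged(self):
        # monotone rise within a narrow window puts the optimum on the edge
        fit = _fit_from_params(11, {"a": 0.0, "b": 0.1, "c": -0.001},
                               5.0, 15.0, n=8)
        _, _, flags = t_opt(fit, window=(5.0, 15.0))
        assert "boundary optimum" in flags


class TestT50:
    def test_gaussian_half_width_closed_form(self, gaussian_fit):
        t50lo, t50hi, flags = t50_limits(gaussian_fit)
        half_width = 5.0 * math.sqrt(2 * math.log(2))
        assert t50lo == pytest.approx(20.0 - half_width, abs=1e-3)
        assert t50hi == pytest.approx(20.0 + half_width, abs=1e-3)

    def test_quadratic_closed_form(self):
        fit = _fit_from_params(11, {"a": -3.0, "b": 4.0, "c": -1.0},
                               1.05, 2.95, n=12)
        t50lo, t50hi, _ = t50_limits(fit)
        assert t50lo == pytest.approx(2 - math.sqrt(2) / 2, abs=1e-3)
        assert t50hi == pytest.approx(2 + math.sqrt(2) / 2, abs=1e-3)

    def test_sine_limits_match_bisection_oracle(self):
        params = {"r_max": 0.9, "t_min": 2.0, "t_max": 30.0,
                  "a": 1.3, "b": 0.8}
        fit = _fit_from_params(15, params, 4.0, 28.0)
        topt, rmax, _ = t_opt(fit)
        t50lo, t50hi, _ = t50_limits(fit)
        grid = np.arange(2.0, 30.0, 0.001)
        vals = tp.evaluate(15, params, grid) - 0.5 * rmax
        sign_changes = np.flatnonzero(np.diff(np.sign(vals)) != 0)
        roots = grid[sign_changes]
        lo_oracle = roots[roots < topt].max()
        hi_oracle = roots[roots > topt].min()
        assert t50lo == pytest.approx(lo_oracle, abs=0.01)
        assert t50hi == pytest.approx(hi_oracle, abs=0.01)


class TestCtLimits:
    def test_ratkowsky_returns_fitted_limits(self):
        params = {"a": 0.004, "b": 0.15, "t_min": 3.0, "t_max": 34.0}
        fit = _fit_from_params(13, params, 5.0, 33.0)
        ctlo, cthi, _ = ct_limits(fit)
        assert ctlo == pytest.approx(fit.params["t_min"])
        assert cthi == pytest.approx(fit.params["t_max"])

    def test_gaussian_is_undefined(self, gaussian_fit):
        ctlo, cthi, flags = ct_limits(gaussian_fit)
        assert ctlo is None and cthi is None
        assert any("asymptotic" in f for f in flags)

    def test_quadratic_roots_closed_form(self):
        fit = _fit_from_params(11, {"a": -3.0, "b": 4.0, "c": -1.0},
                               1.05, 2.95, n=12)
        ctlo, cthi, _ = ct_limits(fit)
        assert ctlo == pytest.approx(1.0, abs=1e-3)
        assert cthi == pytest.approx(3.0, abs=1e-3)


class TestShapeStats:
    def test_gaussian_is_symmetric(self, gaussian_fit):
        act, deact, skew, source, flags = shape_stats(gaussian_fit)
        assert deact == pytest.approx(-act, rel=1e-6)
        assert skew == pytest.approx(0.0, abs=1e-9)
        assert source == "t50"  # asymptotic model falls back to t50 bounds

    def test_mean_derivative_converges_to_secant_slope(self):
        from tpcfit import cardinal as C
        fit = _fit_from_params(11, {"a": -3.0, "b": 4.0, "c": -1.0},
                               1.05, 2.95, n=12)
        topt, _, _ = t_opt(fit)
        ctlo, _, _ = ct_limits(fit)
        grid = np.linspace(ctlo, topt, 10_000)
        mean_deriv = float(np.mean(tp.derivative(11, fit.params, grid)))
        secant = ((fit.predict(topt)[0] - fit.predict(ctlo)[0])
                  / (topt - ctlo))
        assert mean_deriv == pytest.approx(secant, rel=1e-3)

    def test_sine_skew_sign_matches_dense_grid(self):
        params = {"r_max": 1.0, "t_min": 3.0, "t_max": 33.0,
                  "a": 2.0, "b": 1.0}
        fit = _fit_from_params(15, params, 4.5, 32.0)
        act, deact, skew, *_ = shape_stats(fit)
        topt, _, _ = t_opt(fit)
        lo = np.linspace(params["t_min"], topt, 5000)[1:]
        hi = np.linspace(topt, params["t_max"], 5000)[:-1]
        dense = (np.mean(tp.derivative(15, params, lo))
                 + np.mean(tp.derivative(15, params, hi)))
        assert np.sign(skew) == np.sign(dense)
        assert skew < 0  # peak shifted toward t_max: steeper deactivation


class TestClosedFormAgreementRandomDraws:
    def test_gaussian_and_quadratic_over_random_parameters(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            a = rng.uniform(0.3, 2.0)
            b = rng.uniform(2.0, 8.0)
            t_ref = rng.uniform(12.0, 28.0)
            fit = _fit_from_params(8, {"a": a, "b": b, "t_ref": t_ref},
                                   t_ref - 2.5 * b, t_ref + 2.5 * b)
            topt, rmax, _ = t_opt(fit)
            assert topt == pytest.approx(t_ref, abs=1e-3)
            t50lo, t50hi, _ = t50_limits(fit, topt)
            hw = b * math.sqrt(2 * math.log(2))
            assert t50lo == pytest.approx(t_ref - hw, abs=1e-3)
            assert t50hi == pytest.approx(t_ref + hw, abs=1e-3)


class TestOrderingInvariants:
    def test_t50_brackets_topt_across_models(self, noiseless_fits):
        for mid, fit in noiseless_fits.items():
            topt, _, _ = t_opt(fit)
            t50lo, t50hi, _ = t50_limits(fit, topt)
            if t50lo is not None:
                assert t50lo < topt
            if t50hi is not None:
                assert topt < t50hi

    def test_cardinal_ordering_chain(self, noiseless_fits):
        for mid, fit in noiseless_fits.items():
            e = cardinal_estimates(fit)
            if e.ct_min is not None and e.t50_min is not None:
                assert e.ct_min < e.t50_min < e.t_opt
            if e.ct_max is not None and e.t50_max is not None:
                assert e.t_opt < e.t50_max < e.ct_max


class TestConsensus:
    def test_two_model_equal_weights(self, noiseless_fits):
        fits = [noiseless_fits[8], noiseless_fits[11]]
        weights = {8: 0.5, 11: 0.5}
        cons = consensus(fits, weights, np.linspace(10, 30, 11))
        e8 = cardinal_estimates(fits[0])
        e11 = cardinal_estimates(fits[1])
        expected = 0.5 * e8.t_opt + 0.5 * e11.t_opt
        assert cons.weighted_mean["t_opt"] == pytest.approx(expected)
        assert cons.deviations["t_opt"][8] == pytest.approx(
            e8.t_opt - expected)

    def test_degenerate_weight_reduces_to_single_model(self, noiseless_fits):
        fits = [noiseless_fits[8], noiseless_fits[11]]
        cons = consensus(fits, {8: 1.0, 11: 0.0}, np.linspace(10, 30, 11))
        e8 = cardinal_estimates(fits[0])
        assert cons.weighted_mean["t_opt"] == pytest.approx(e8.t_opt)
        e11 = cardinal_estimates(fits[1])
        assert cons.deviations["t_opt"][11] == pytest.approx(
            e11.t_opt - e8.t_opt)

    def test_weighted_deviations_sum_to_zero(self, paper_like_fits):
        weights = akaike_weights(paper_like_fits)
        T = paper_like_fits[0].temperatures
        cons = consensus(paper_like_fits, weights, T)
        for q, devs in cons.deviations.items():
            sub = {m: weights[m] for m in devs}
            tot = sum(sub.values())
            s = sum(w / tot * devs[m] for m, w in sub.items())
            assert s == pytest.approx(0.0, abs=1e-9), q

    def test_zero_weight_model_never_changes_consensus(self, noiseless_fits):
        T = np.linspace(10, 30, 11)
        base = consensus([noiseless_fits[8], noiseless_fits[11]],
                         {8: 0.6, 11: 0.4}, T)
        extended = consensus(
            [noiseless_fits[8], noiseless_fits[11], noiseless_fits[12]],
            {8: 0.6, 11: 0.4, 12: 0.0}, T)
        for q in base.weighted_mean:
            assert extended.weighted_mean[q] == pytest.approx(
                base.weighted_mean[q], abs=1e-12)
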