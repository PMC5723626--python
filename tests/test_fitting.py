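"""Least-squares fitting, information criteria, ranking, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

import tpcfit as tp
from tpcfit import models as M
from tpcfit.fitting import (ThermalModelEnsemble, ThermalResponseRegressor,
                            akaike_weights, cluster_predictions,
                            compare_ranks_across_datasets, fit_all, fit_model,
                            information_criteria, rank_models)


class TestInformationCriteria:
    def test_worked_example(self):
        loglik, aic, aicc, bic, flags = information_criteria(n=10, k=3,
                                                             rss=0.1)
        assert loglik == pytest.approx(8.8365, abs=1e-3)
        assert aic == pytest.approx(-9.6729, abs=1e-3)
        assert aicc == pytest.approx(-1.6729, abs=1e-3)
        assert bic == pytest.approx(-8.4626, abs=1e-3)
        assert not flags

    def test_aicc_undefined_when_denominator_vanishes(self):
        # n=8, k=6 -> n - k' - 1 = 0
        *_, aicc, _, flags = information_criteria(n=8, k=6, rss=0.5)
        assert math.isnan(aicc)
        assert any("aicc" in f for f in flags)

    def test_equal_rss_bic_difference_is_log_n(self):
        n = 25
        *_, bic3, _ = information_criteria(n=n, k=3, rss=0.2)
        *_, bic4, _ = information_criteria(n=n, k=4, rss=0.2)
        assert bic4 - bic3 == pytest.approx(math.log(n), rel=1e-12)

    def test_perfect_fit_flagged_degenerate(self):
        *_, flags = information_criteria(n=10, k=3, rss=0.0)
        assert "degenerate perfect fit" in flags


class TestFitModel:
    def test_gaussian_parameter_recovery(self):
        T = np.linspace(5, 35, 30)
        truth = {"a": 1.0, "b": 5.0, "t_ref": 20.0}
        curve = tp.PreparedCurve("g", T, tp.evaluate(8, truth, T))
        fit = fit_model(8, curve)
        assert fit.converged
        assert fit.rss < 1e-10
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, abs=1e-4)

    def test_quadratic_on_exact_parabola(self):
        # rate = T^2 exactly; compare with the normal-equations solution
        T = np.array([1.0, 2.0, 3.0, 4.0])
        curve = tp.PreparedCurve("q", T, T ** 2)
        fit = fit_model(11, curve)
        coef, *_ = np.linalg.lstsq(np.vstack([np.ones_like(T), T, T**2]).T,
                                   T ** 2, rcond=None)
        assert fit.params["a"] == pytest.approx(coef[0], abs=1e-8)
        assert fit.params["b"] == pytest.approx(coef[1], abs=1e-8)
        assert fit.params["c"] == pytest.approx(coef[2], abs=1e-8)
        assert fit.rss < 1e-16

    def test_insufficient_data_raises(self):
        T = np.linspace(10, 30, 5)
        curve = tp.PreparedCurve("s", T, np.full(5, 0.5))
        with pytest.raises(ValueError, match="insufficient data"):
            fit_model(15, curve)  # 5 parameters need > 5 points

    def test_fit_is_deterministic(self, paper_like_curve):
        f1 = fit_model(9, paper_like_curve, random_state=3)
        f2 = fit_model(9, paper_like_curve, random_state=3)
        assert f1.params == f2.params
        assert f1.rss == f2.rss

    def test_converged_fit_is_local_minimum(self, gaussian_fit):
        base = gaussian_fit.rss
        T, y = gaussian_fit.temperatures, gaussian_fit.observed
        for name, v in gaussian_fit.params.items():
            for sign in (+1, -1):
                p = dict(gaussian_fit.params)
                p[name] = v + sign * 1e-6 * max(abs(v), 1.0)
                rss = float(np.sum((y - tp.evaluate(8, p, T)) ** 2))
                assert rss >= base - 1e-10 * max(base, 1e-12)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = ThermalResponseRegressor(model=8, random_state=5)
        params = est.get_params()
        assert params["model"] == 8
        est2 = ThermalResponseRegressor(**params)
        assert est2.get_params() == params

    def test_fit_predict_column_vector(self):
        T = np.linspace(5, 35, 30)[:, None]
        y = tp.evaluate(8, {"a": 1.0, "b": 5.0, "t_ref": 20.0}, T[:, 0])
        est = ThermalResponseRegressor(model=8).fit(T, y)
        np.testing.assert_allclose(est.predict(T), y, atol=1e-6)
        assert est.converged_ and est.rss_ < 1e-10

    def test_ensemble_fits_and_selects(self, paper_like_curve):
        ens = ThermalModelEnsemble(random_state=0).fit(
            paper_like_curve.temperatures, paper_like_curve.rates)
        assert len(ens.fits_) == 12
        assert ens.best_model_id_ in range(4, 16)
        w = ens.predict(paper_like_curve.temperatures, which="weighted")
        assert w.shape == paper_like_curve.temperatures.shape


def test_fit_all_skips_undersized_models():
    T = np.linspace(10, 30, 5)
    rates = tp.evaluate(8, {"a": 1.0, "b": 5.0, "t_ref": 20.0}, T)
    curve = tp.PreparedCurve("small", T, rates)
    fits = fit_all(curve)
    ids = {f.model_id for f in fits}
    # only models with <= 4 parameters fit 5 points (n > k)
    assert ids == {8, 11, 12}.union({i for i in (4, 5, 7, 9, 10, 13)})
    assert 6 not in ids and 14 not in ids and 15 not in ids


def test_fit_all_boundary_n_equals_k_plus_one(noiseless_curves):
    curve = noiseless_curves[6]
    sub = tp.PreparedCurve("b", curve.temperatures[:7], curve.rates[:7])
    fits = fit_all(sub)
    assert 6 in {f.model_id for f in fits}  # 7 points > 6 parameters


def test_self_generated_noiseless_rss_is_tiny(noiseless_fits):
    for mid, fit in noiseless_fits.items():
        assert fit.converged, mid
        assert fit.rss < 1e-8, (mid, fit.rss)


def test_master_equation_nests_reduced_form(paper_like_curve):
    """With its low-temperature denaturation term started inactive, the
    six-parameter master equation can only improve on its reduced form."""
    f7 = fit_model(7, paper_like_curve)
    R = M.GAS_CONSTANT
    a6 = (f7.params["a"] * (298.15 / 293.15)
          * math.exp((f7.params["b"] / R) * (1 / 293.15 - 1 / 298.15)))
    start6 = {"a": a6, "b": f7.params["b"], "c": -1.0e6, "d": 250.0,
              "e": f7.params["c"], "f": f7.params["d"]}
    f6 = fit_model(6, paper_like_curve, start=start6)
    assert f6.converged
    assert f6.rss <= f7.rss + 1e-8


class TestAkaikeWeights:
    @staticmethod
    def _fake(mid, aic, k=3):
        return tp.FitResult(model_id=mid, params={}, converged=True, n=10,
                            k=k, rss=1.0, loglik=0.0, aic=aic, aicc=aic,
                            bic=aic, residuals=np.zeros(1),
                            temperatures=np.zeros(1), observed=np.zeros(1))

    def test_delta_two(self):
        w = akaike_weights([self._fake(8, 0.0), self._fake(11, 2.0)])
        assert w[8] == pytest.approx(0.7311, abs=1e-4)
        assert w[11] == pytest.approx(0.2689, abs=1e-4)

    def test_identical_aic_splits_evenly(self):
        w = akaike_weights([self._fake(m, 5.0) for m in (8, 11, 12)])
        assert all(v == pytest.approx(1 / 3) for v in w.values())

    def test_weights_sum_to_one(self):
        w = akaike_weights([self._fake(m, a) for m, a in
                            zip(range(4, 16), np.linspace(-4, 30, 12))])
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_nonconverged_gets_zero(self):
        bad = self._fake(9, -100.0)
        bad.converged = False
        w = akaike_weights([self._fake(8, 0.0), bad])
        assert w[9] == 0.0 and w[8] == 1.0


class TestRankModels:
    _fake = staticmethod(TestAkaikeWeights._fake)

    def test_rank_orders_by_bic(self):
        fits = [self._fake(8, -5.0), self._fake(11, -3.0),
                self._fake(15, -10.0)]
        comp = rank_models(fits)
        assert comp.bic_rank == {15: 1, 8: 2, 11: 3}

    def test_tie_broken_by_fewer_parameters(self):
        comp = rank_models([self._fake(9, 0.0, k=4), self._fake(8, 0.0, k=3)])
        assert comp.bic_rank[8] == 1

    def test_ranks_are_a_permutation(self, paper_like_fits):
        comp = rank_models(paper_like_fits)
        conv = [f for f in paper_like_fits if f.converged]
        assert sorted(comp.bic_rank.values()) == list(range(1, len(conv) + 1))

    def test_rank_invariant_to_loglik_shift(self):
        fits_a = [self._fake(m, a) for m, a in ((8, 1.0), (11, 4.0),
                                                (12, 2.5))]
        fits_b = [self._fake(m, a + 7.0) for m, a in ((8, 1.0), (11, 4.0),
                                                      (12, 2.5))]
        assert rank_models(fits_a).bic_rank == rank_models(fits_b).bic_rank


class TestCompareRanks:
    def test_two_models_five_datasets(self):
        table = pd.DataFrame({"A": [1] * 5, "B": [2] * 5})
        res = compare_ranks_across_datasets(table)
        assert res["H"] == pytest.approx(9.0, abs=1e-9)
        assert res["df"] == 1

    def test_identical_ranks_give_h_zero(self):
        res = compare_ranks_across_datasets(
            pd.DataFrame({"A": [1] * 4, "B": [1] * 4}))
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_posthoc_matches_bruteforce_criterion(self):
        from scipy import stats
        rng = np.random.default_rng(11)
        table = pd.DataFrame({
            "A": rng.integers(1, 4, 12), "B": rng.integers(2, 6, 12),
            "C": rng.integers(5, 9, 12)})
        res = compare_ranks_across_datasets(table, alpha=0.05)
        pooled = stats.rankdata(table.to_numpy().ravel(order="F"))
        n = len(table)
        means = {c: pooled[i * n:(i + 1) * n].mean()
                 for i, c in enumerate(table.columns)}
        N, k = 3 * n, 3
        for i in "ABC":
            for j in "ABC":
                if i >= j:
                    continue
                se = math.sqrt(N * (N + 1) / 12 * (2 / n))
                q = abs(means[i] - means[j]) / se * math.sqrt(2)
                expected = stats.studentized_range.sf(q, k, np.inf) < 0.05
                assert bool(res["significant"].loc[i, j]) == expected


class TestClusterPredictions:
    _fake = staticmethod(TestAkaikeWeights._fake)

    def test_identical_predictions_merge_first_at_zero(self, gaussian_fit):
        import copy
        f2 = copy.deepcopy(gaussian_fit)
        f2.model_id = 9
        f2.params = {"a": gaussian_fit.params["a"],
                     "b": gaussian_fit.params["b"], "c": 2.0,
                     "t_ref": gaussian_fit.params["t_ref"]}
        f3 = copy.deepcopy(gaussian_fit)
        f3.model_id = 11
        f3.params = {"a": 5.0, "b": 0.0, "c": 0.0}
        T = np.linspace(10, 30, 9)
        out = cluster_predictions([gaussian_fit, f2, f3], T)
        Z = out["linkage"]
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_distance_is_euclidean(self):
        from scipy.spatial.distance import euclidean
        a = np.array([0.1, 0.2])
        b = np.array([0.4, 0.6])
        assert euclidean(a, b) == pytest.approx(0.5)

    def test_three_vector_ward_matches_lance_williams(self, gaussian_fit):
        import copy
        fits = []
        preds = [np.array([0.0, 0.0, 1.0]), np.array([0.1, 0.0, 1.0]),
                 np.array([2.0, 2.0, 2.0])]
        # build fits whose quadratic predictions equal the target vectors
        T = np.array([0.0, 1.0, 2.0])
        for i, v in enumerate(preds):
            coef = np.linalg.solve(np.vstack([np.ones(3), T, T**2]).T, v)
            f = copy.deepcopy(gaussian_fit)
            f.model_id = 11
            f.params = {"a": coef[0], "b": coef[1], "c": coef[2]}
            fits.append(f)
        out = cluster_predictions(fits, T)
        Z = out["linkage"]
        d01 = np.linalg.norm(preds[0] - preds[1])
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(d01, rel=1e-9)
        # Lance-Williams Ward update for the final merge of {0,1} with 2
        d02 = np.linalg.norm(preds[0] - preds[2])
        d12 = np.linalg.norm(preds[1] - preds[2])
        expected = math.sqrt((2 * d02**2 + 2 * d12**2 - d01**2) / 3)
        assert Z[1, 2] == pytest.approx(expected, rel=1e-9)

    def test_fewer_than_two_fits_rejected(self, gaussian_fit):
        with pytest.raises(ValueError):
            cluster_predictions([gaussian_fit], np.array([10.0, 20.0]))
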