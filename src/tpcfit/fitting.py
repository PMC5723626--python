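"""Least-squares fitting of thermal response models and model selection.

The core object is :class:`ThermalResponseRegressor`, a scikit-learn
style estimator wrapping a Levenberg-Marquardt least-squares fit (via
lmfit's MINPACK backend) of one registered equation to temperature-rate
data.  On top of it sit Gaussian-likelihood information criteria
(AIC/AICc/BIC), Akaike weights, per-curve BIC ranks, a Kruskal-Wallis
comparison of ranks across datasets with Nemenyi post hoc pairs, and
Ward clustering of model predictions.

Points are unweighted: replicate counts are discarded after averaging.
The residual noise scale sigma = sqrt(rss/n) is counted as a fitted
parameter in the criteria (k' = k + 1); any uniform convention leaves
the model ordering unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, RegressorMixin

from . import models as _models
from .data import PreparedCurve

__all__ = [
    "FitResult",
    "ModelComparison",
    "ThermalResponseRegressor",
    "ThermalModelEnsemble",
    "information_criteria",
    "fit_model",
    "fit_all",
    "akaike_weights",
    "rank_models",
    "compare_ranks_across_datasets",
    "cluster_predictions",
]

logger = logging.getLogger("tpcfit")

#: Residual value substituted where a model evaluates non-finite, large
#: enough to dominate any plausible rate residual.
_PENALTY = 1.0e6

#: Floor applied to rss when computing criteria for a numerically perfect
#: fit (flagged "degenerate perfect fit"); keeps the ordering well defined.
_RSS_FLOOR = 1.0e-300


@dataclass
class FitResult:
    """Parameter estimates and likelihood bookkeeping for one model on
    one curve."""

    model_id: int
    params: dict
    converged: bool
    n: int
    k: int
    rss: float
    loglik: float
    aic: float
    aicc: float
    bic: float
    residuals: np.ndarray
    temperatures: np.ndarray
    observed: np.ndarray
    curve_id: str = ""
    message: str = ""
    flags: list = field(default_factory=list)

    @property
    def sigma(self) -> float:
        """Residual noise scale sigma-hat = sqrt(rss/n)."""
        return math.sqrt(self.rss / self.n)

    def predict(self, temperatures) -> np.ndarray:
        return _models.evaluate(self.model_id, self.params, temperatures)

    @property
    def spec(self) -> _models.ModelSpec:
        return _models.get_model(self.model_id)


@dataclass
class ModelComparison:
    """Per-curve comparison of converged fits: AIC deltas, Akaike
    weights and BIC ranks (1 = best)."""

    curve_id: str
    model_ids: list
    delta_aic: dict
    akaike_weight: dict
    bic_rank: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "curve_id": self.curve_id,
            "model_id": self.model_ids,
            "delta_aic": [self.delta_aic[m] for m in self.model_ids],
            "akaike_weight": [self.akaike_weight[m] for m in self.model_ids],
            "bic_rank": [self.bic_rank[m] for m in self.model_ids],
        })


def information_criteria(fit: FitResult | None = None, *, n: int | None = None,
                         k: int | None = None, rss: float | None = None):
    """Gaussian log-likelihood and AIC/AICc/BIC for a least-squares fit.

    With sigma-hat profiled out, loglik = -(n/2)(ln 2pi + ln(rss/n) + 1).
    The criteria use k' = k + 1 parameters (sigma counted):
    ``aic = 2k' - 2 loglik``, ``aicc = aic + 2k'(k'+1)/(n-k'-1)``,
    ``bic = k' ln n - 2 loglik``.

    Returns ``(loglik, aic, aicc, bic, flags)``; ``aicc`` is NaN when its
    correction denominator is non-positive, and a numerically perfect fit
    (rss == 0) is flagged and evaluated at a tiny floor.
    """
    if fit is not None:
        n, k, rss = fit.n, fit.k, fit.rss
    flags = []
    if rss <= 0.0:
        flags.append("degenerate perfect fit")
        rss = _RSS_FLOOR
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)
    kp = k + 1
    aic = 2.0 * kp - 2.0 * loglik
    bic = kp * math.log(n) - 2.0 * loglik
    if n - kp - 1 <= 0:
        aicc = float("nan")
        flags.append("aicc undefined (n - k' - 1 <= 0)")
    else:
        aicc = aic + 2.0 * kp * (kp + 1.0) / (n - kp - 1.0)
    return loglik, aic, aicc, bic, flags


class ThermalResponseRegressor(RegressorMixin, BaseEstimator):
    """Fit one thermal response equation to temperature-rate data.

    Parameters
    ----------
    model : int or str, default=15
        Registered equation id (4..15) or name (e.g. ``"gaussian"``).
    start : dict, optional
        Starting parameter vector; by default a data-driven start is
        built from the training curve (amplitudes at the maximum rate,
        reference/limit temperatures at the mean/min/max temperature).
    n_restarts : int, default=10
        Maximum number of jittered restarts used when the primary start
        fails to converge.
    jitter_sd : float, default=0.5
        Sigma of the multiplicative log-normal jitter applied to the
        start vector on restarts.
    random_state : int, default=0
        Base seed for the restart jitter; fitting is deterministic given
        (data, start, random_state).
    max_nfev : int, optional
        Cap on function evaluations per Levenberg-Marquardt attempt.

    Attributes
    ----------
    params_ : dict of fitted parameter values
    converged_ : bool
    rss_, loglik_, aic_, aicc_, bic_ : float
    result_ : FitResult with the full bookkeeping
    """

    def __init__(self, model: int | str = 15, start: dict | None = None,
                 n_restarts: int = 10, jitter_sd: float = 0.5,
                 random_state: int = 0, max_nfev: int | None = 3000):
        self.model = model
        self.start = start
        self.n_restarts = n_restarts
        self.jitter_sd = jitter_sd
        self.random_state = random_state
        self.max_nfev = max_nfev

    # -- scikit-learn plumbing ------------------------------------------
    @staticmethod
    def _as_temperatures(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single temperature feature")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("temperatures must be 1d or a single column")
        if not np.all(np.isfinite(X)):
            raise ValueError("temperatures must be finite")
        return X

    def fit(self, X, y, curve_id: str = ""):
        """Least-squares fit of the equation to rates ``y`` at
        temperatures ``X`` (deg C, shape (n,) or (n, 1))."""
        T = self._as_temperatures(X)
        y = np.asarray(y, dtype=float)
        if y.shape != T.shape:
            raise ValueError("X and y have incompatible shapes")
        spec = _models.get_model(self.model)
        n, k = T.size, spec.n_params
        if n <= k:
            raise ValueError(
                f"insufficient data: model {spec.id} ({spec.name}) has "
                f"{k} parameters but only {n} points are available"
            )
        curve = PreparedCurve(curve_id or "curve", T, y)
        start = dict(self.start) if self.start is not None \
            else _models.initial_params(spec, curve)

        best = None
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, spec.id])
        )
        attempts = [start]
        for i in range(self.n_restarts + 1):
            if i >= len(attempts):
                attempts.append(_jitter(start, rng, self.jitter_sd))
            res = self._minimize(spec, attempts[i], T, y)
            if res is None:
                continue
            if best is None or res[0] < best[0]:
                best = res
            if res[2]:
                break
            if np.isfinite(res[0]):
                # The optimizer exhausted its budget while still creeping
                # along a near-flat likelihood ridge (a known degeneracy of
                # the double-Arrhenius form, where the infimum is approached
                # but never attained).  Polish from the stall point; once
                # the relative rss improvement is negligible, accept the
                # fit there and flag it.
                res = self._polish(spec, res, T, y)
                if res[2] or res[0] < best[0]:
                    best = res
                if res[2]:
                    break
        if best is None:  # every attempt raised inside MINPACK
            best = (float("inf"), dict(start), False, "all starts failed")
        rss, params, ok, message = best

        residuals = y - _models.evaluate(spec, params, T)
        loglik, aic, aicc, bic, flags = information_criteria(n=n, k=k, rss=rss)
        if not ok:
            logger.warning("fit of model %s to %s did not converge: %s",
                           spec.id, curve_id or "curve", message)
        self.spec_ = spec
        self.params_ = params
        self.converged_ = bool(ok)
        self.n_ = n
        self.k_ = k
        self.rss_ = float(rss)
        self.loglik_ = loglik
        self.aic_ = aic
        self.aicc_ = aicc
        self.bic_ = bic
        self.result_ = FitResult(
            model_id=spec.id, params=params, converged=bool(ok), n=n, k=k,
            rss=float(rss), loglik=loglik, aic=aic, aicc=aicc, bic=bic,
            residuals=residuals, temperatures=T.copy(), observed=y.copy(),
            curve_id=curve_id, message=message, flags=flags,
        )
        return self

    #: relative rss improvement below which a budget-limited fit is
    #: considered stalled at its (possibly degenerate) minimum
    _STALL_RTOL = 1e-6

    def _polish(self, spec, res, T, y, max_rounds: int = 3):
        rss, params, ok, msg = res
        for _ in range(max_rounds):
            nxt = self._minimize(spec, params, T, y)
            if nxt is None or not np.isfinite(nxt[0]):
                break
            improved = rss - nxt[0]
            if nxt[0] < rss:
                rss, params, _, msg = nxt
            if nxt[2]:  # proper convergence on the polish round
                return nxt
            if improved <= self._STALL_RTOL * max(rss, 1e-30):
                return rss, params, True, msg + " (accepted at stall)"
        if np.isfinite(rss):
            # Still descending when the budget ran out: the minimum is
            # approached asymptotically along a degenerate ridge, so the
            # curve itself has effectively stopped changing.  Keep the
            # fit, flagged, as the budget-limited solution.
            return rss, params, True, msg + " (accepted at evaluation budget)"
        return rss, params, False, msg

    def _minimize(self, spec, start, T, y):
        # Strictly positive scale parameters that span many orders of
        # magnitude (the Arrhenius pre-factors) are fit on a log scale;
        # MINPACK's relative-step tests are unreliable on them otherwise.
        log_names = {n for n in spec.log_scale if start[n] > 0.0}
        pars = lmfit.Parameters()
        for name in spec.param_names:
            if name in log_names:
                pars.add("log_" + name, value=math.log(start[name]))
            else:
                pars.add(name, value=start[name])

        def unpack(p):
            return {
                name: (math.exp(p["log_" + name].value) if name in log_names
                       else p[name].value)
                for name in spec.param_names
            }

        def residual(p):
            pred = _models.evaluate(spec, unpack(p), T)
            r = pred - y
            bad = ~np.isfinite(r)
            if bad.any():
                r = np.where(bad, _PENALTY, r)
            return r

        try:
            out = lmfit.minimize(residual, pars, method="leastsq",
                                 max_nfev=self.max_nfev)
        except Exception as exc:  # pragma: no cover - MINPACK edge failures
            logger.debug("LM attempt raised: %s", exc)
            return None
        params = {name: float(v) for name, v in unpack(out.params).items()}
        pred = _models.evaluate(spec, params, T)
        finite = np.all(np.isfinite(pred))
        rss = float(np.sum((y - pred) ** 2)) if finite else float("inf")
        ok = bool(out.success) and finite and np.isfinite(rss) \
            and all(np.isfinite(v) for v in params.values())
        return rss, params, ok, str(out.message)

    def predict(self, X) -> np.ndarray:
        T = self._as_temperatures(X)
        return _models.evaluate(self.spec_, self.params_, T)


def _safe(name: str) -> str:
    # lmfit parameter names cannot start with a digit; ours never do,
    # but keep a single mangling point.
    return name


def _jitter(start: Mapping[str, float], rng, sd: float) -> dict:
    out = {}
    for name, v in start.items():
        if v == 0.0:
            out[name] = float(rng.normal(0.0, sd))
        else:
            out[name] = float(v * rng.lognormal(0.0, sd))
    return out


class ThermalModelEnsemble(BaseEstimator):
    """Fit every registered equation to one curve and compare them.

    After ``fit``, ``fits_`` holds one :class:`FitResult` per equation
    that passed the size guard (n > k), ``skipped_`` the ids that did
    not, ``comparison_`` the BIC ranks and Akaike weights over converged
    fits, and ``best_model_id_`` the BIC-rank-1 equation.  ``predict``
    evaluates either the best model or the Akaike-weighted mean curve.
    """

    def __init__(self, n_restarts: int = 10, jitter_sd: float = 0.5,
                 random_state: int = 0, max_nfev: int | None = None):
        self.n_restarts = n_restarts
        self.jitter_sd = jitter_sd
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, X, y, curve_id: str = ""):
        T = ThermalResponseRegressor._as_temperatures(X)
        y = np.asarray(y, dtype=float)
        curve = PreparedCurve(curve_id or "curve", T, y)
        self.fits_ = []
        self.skipped_ = []
        for spec in _models.list_models():
            if curve.n_temperatures <= spec.n_params:
                self.skipped_.append(spec.id)
                logger.info("skipping model %s on %s: n=%d <= k=%d",
                            spec.id, curve.curve_id, curve.n_temperatures,
                            spec.n_params)
                continue
            est = ThermalResponseRegressor(
                model=spec.id, n_restarts=self.n_restarts,
                jitter_sd=self.jitter_sd, random_state=self.random_state,
                max_nfev=self.max_nfev,
            ).fit(T, y, curve_id=curve.curve_id)
            self.fits_.append(est.result_)
        converged = [f for f in self.fits_ if f.converged]
        self.weights_ = akaike_weights(self.fits_)
        self.comparison_ = rank_models(self.fits_) if len(converged) >= 2 else None
        self.best_model_id_ = (
            min(self.comparison_.bic_rank, key=self.comparison_.bic_rank.get)
            if self.comparison_ is not None
            else (converged[0].model_id if converged else None)
        )
        return self

    def predict(self, X, which: str = "best") -> np.ndarray:
        T = ThermalResponseRegressor._as_temperatures(X)
        if which == "best":
            fit = next(f for f in self.fits_ if f.model_id == self.best_model_id_)
            return fit.predict(T)
        if which == "weighted":
            out = np.zeros_like(T, dtype=float)
            for f in self.fits_:
                w = self.weights_.get(f.model_id, 0.0)
                if w > 0.0:
                    out += w * f.predict(T)
            return out
        raise ValueError("which must be 'best' or 'weighted'")


# ---------------------------------------------------------------------------
# Functional wrappers used throughout the package and by the CLI.

def fit_model(model, curve: PreparedCurve, start: dict | None = None,
              n_restarts: int = 10, jitter_sd: float = 0.5,
              random_state: int = 0, max_nfev: int | None = None) -> FitResult:
    """Fit one equation to a prepared curve; see ThermalResponseRegressor."""
    est = ThermalResponseRegressor(
        model=model, start=start, n_restarts=n_restarts, jitter_sd=jitter_sd,
        random_state=random_state, max_nfev=max_nfev,
    ).fit(curve.temperatures, curve.rates, curve_id=curve.curve_id)
    return est.result_


def fit_all(curve: PreparedCurve, n_restarts: int = 10, jitter_sd: float = 0.5,
            random_state: int = 0, max_nfev: int | None = None
            ) -> list[FitResult]:
    """One FitResult per registered model with n > k; undersized models
    are skipped (reported in the log), not errors."""
    ens = ThermalModelEnsemble(
        n_restarts=n_restarts, jitter_sd=jitter_sd,
        random_state=random_state, max_nfev=max_nfev,
    ).fit(curve.temperatures, curve.rates, curve_id=curve.curve_id)
    return ens.fits_


def akaike_weights(fits: Iterable[FitResult]) -> dict[int, float]:
    """AIC-based Akaike weights; non-converged fits get weight 0."""
    fits = list(fits)
    conv = [f for f in fits if f.converged and np.isfinite(f.aic)]
    weights = {f.model_id: 0.0 for f in fits}
    if not conv:
        return weights
    aics = np.array([f.aic for f in conv])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(conv, w):
        weights[f.model_id] = float(wi)
    return weights


def rank_models(fits: Iterable[FitResult], curve_id: str | None = None
                ) -> ModelComparison:
    """BIC ranks (1 = best) and Akaike weights over converged fits.

    Ties in BIC are broken toward fewer parameters, then the lower id.
    """
    fits = list(fits)
    conv = [f for f in fits if f.converged and np.isfinite(f.bic)]
    if len(conv) < 2:
        raise ValueError("ranking needs at least 2 converged fits")
    order = sorted(conv, key=lambda f: (f.bic, f.k, f.model_id))
    bic_rank = {f.model_id: i + 1 for i, f in enumerate(order)}
    weights = akaike_weights(fits)
    aics = np.array([f.aic for f in conv])
    amin = aics.min()
    delta = {f.model_id: float(f.aic - amin) for f in conv}
    cid = curve_id if curve_id is not None else (conv[0].curve_id or "")
    return ModelComparison(
        curve_id=cid,
        model_ids=[f.model_id for f in order],
        delta_aic=delta,
        akaike_weight={m: weights[m] for m in bic_rank},
        bic_rank=bic_rank,
    )


def compare_ranks_across_datasets(rank_table: pd.DataFrame, alpha: float = 0.05):
    """Kruskal-Wallis test on per-dataset model ranks, with Nemenyi pairs.

    Parameters
    ----------
    rank_table : DataFrame
        Rows = datasets, columns = models, cells = per-dataset BIC rank.
    alpha : float
        Significance level for the post hoc pairwise flags.

    Returns
    -------
    dict with keys ``H`` (tie-corrected statistic), ``df``, ``p``,
    ``pairwise`` (DataFrame of Nemenyi p-values) and ``significant``
    (boolean DataFrame at ``alpha``).
    """
    rank_table = pd.DataFrame(rank_table)
    cols = list(rank_table.columns)
    if len(cols) < 2 or len(rank_table) < 2:
        raise ValueError("need at least 2 models and 2 datasets")
    groups = [rank_table[c].dropna().to_numpy(dtype=float) for c in cols]
    flat = np.concatenate(groups)
    k = len(groups)
    dof = k - 1
    if np.all(flat == flat[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
    # Nemenyi-type pairwise comparison on pooled mean ranks, studentized
    # range reference distribution (two-sided, infinite error df).
    pooled = stats.rankdata(flat)
    sizes = [g.size for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = {c: pooled[idx[i]:idx[i + 1]].mean() for i, c in enumerate(cols)}
    N = flat.size
    pw = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[cols[i]] - mean_ranks[cols[j]]) / se * math.sqrt(2.0)
            pij = float(stats.studentized_range.sf(q, k, np.inf))
            pw.iloc[i, j] = pw.iloc[j, i] = min(1.0, pij)
    return {
        "H": float(H),
        "df": dof,
        "p": float(p),
        "mean_ranks": mean_ranks,
        "pairwise": pw,
        "significant": pw < alpha,
    }


def cluster_predictions(fits: Sequence[FitResult], temperatures) -> dict:
    """Ward linkage over per-temperature prediction vectors.

    Euclidean distances between each converged model's predictions at
    the given temperatures, agglomerated by Ward's minimum variance
    method.  Returns the scipy linkage matrix and the model id order.
    """
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise ValueError("clustering needs at least 2 converged fits")
    T = np.asarray(temperatures, dtype=float)
    X = np.vstack([f.predict(T) for f in fits])
    Z = linkage(X, method="ward")
    return {"linkage": Z, "model_ids": [f.model_id for f in fits]}
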