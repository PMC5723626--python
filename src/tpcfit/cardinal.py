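"""Cardinal temperatures and curve-shape statistics from fitted models.

From a fitted thermal response curve this module extracts:

* ``t_opt`` and ``r_max`` -- the optimum temperature and the rate there,
  by bounded numeric maximization;
* ``t50_min``/``t50_max`` -- the nearest temperatures below/above the
  optimum where the curve crosses half the maximum rate;
* ``ct_min``/``ct_max`` -- the zero crossings bounding the biokinetic
  range (fitted parameters for the equations that carry them;
  undefined for asymptotic equations that never reach zero);
* activation / deactivation -- the mean slope of the curve over the
  suboptimal and supra-optimal ranges -- and their signed sum, the skew
  (negative when the supra-optimal decline is steeper than the rise).

Akaike-weighted consensus values across models, and each model's signed
deviation from the consensus, quantify how much the choice of equation
alone moves the estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize

from . import models as _models
from .fitting import FitResult

__all__ = [
    "CardinalEstimates",
    "ConsensusEstimates",
    "default_window",
    "t_opt",
    "t50_limits",
    "ct_limits",
    "shape_stats",
    "cardinal_estimates",
    "consensus",
]

#: Number of grid points for the mean-derivative (activation) integrals.
DERIV_GRID = 100

#: Coarse-grid size used to localize extrema/roots before refinement.
_SCAN = 2001

_XTOL = 1e-8  # refinement tolerance, well below the 1e-4 degC contract


@dataclass
class CardinalEstimates:
    model_id: int
    t_opt: float
    r_max: float
    ct_min: float | None = None
    ct_max: float | None = None
    t50_min: float | None = None
    t50_max: float | None = None
    activation: float | None = None
    deactivation: float | None = None
    skew: float | None = None
    bound_source: str = ""
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "t_opt": self.t_opt, "r_max": self.r_max,
            "ct_min": self.ct_min, "ct_max": self.ct_max,
            "t50_min": self.t50_min, "t50_max": self.t50_max,
            "activation": self.activation, "deactivation": self.deactivation,
            "skew": self.skew,
        }


@dataclass
class ConsensusEstimates:
    curve_id: str
    weighted_mean: dict
    deviations: dict          # quantity -> {model_id: signed deviation}
    rate_deviation: dict      # model_id -> mean |pred - weighted mean| (rate units)
    rate_deviation_pct: dict  # model_id -> same, as % of the consensus maximum
    weights: dict
    flags: list = field(default_factory=list)


def default_window(fit: FitResult) -> tuple[float, float]:
    """Search window [min - span, max + span] around the fitted data's
    temperature range, where span is that range's width."""
    lo = float(fit.temperatures.min())
    hi = float(fit.temperatures.max())
    span = hi - lo
    return lo - span, hi + span


def _search_window(fit: FitResult, window: tuple[float, float]) -> tuple[float, float]:
    # Equations carrying fitted thermal limits are only meaningful on
    # [t_min, t_max]; outside it eq 13 rises again and eq 15 is zero by
    # construction, so the search is clipped to the biokinetic interval.
    lo, hi = window
    p = fit.params
    if "t_min" in p and "t_max" in p and p["t_max"] > p["t_min"]:
        lo = max(lo, p["t_min"])
        hi = min(hi, p["t_max"])
    return lo, hi


def t_opt(fit: FitResult, window: tuple[float, float] | None = None
          ) -> tuple[float, float, list]:
    """Temperature of the predicted maximum rate, by bounded maximization.

    Returns ``(t_opt, r_max, flags)``; a maximum on the window boundary
    is flagged ``"boundary optimum"``.
    """
    if window is None:
        window = default_window(fit)
    lo, hi = _search_window(fit, window)
    grid = np.linspace(lo, hi, _SCAN)
    vals = fit.predict(grid)
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, _SCAN - 1)]

    def neg(t):
        v = fit.predict(t)[0]
        return -v if np.isfinite(v) else np.inf

    res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded",
                                   options={"xatol": _XTOL})
    topt = float(res.x)
    rmax = float(fit.predict(topt)[0])
    flags = []
    edge = (hi - lo) * 1e-3
    if topt - lo < edge or hi - topt < edge:
        flags.append("boundary optimum")
    return topt, rmax, flags


def _nearest_root(fit: FitResult, level: float, start: float, stop: float):
    """Nearest temperature between start (exclusive) and stop where the
    fitted rate crosses ``level``, scanning outward from ``start``."""
    grid = np.linspace(start, stop, _SCAN)
    vals = fit.predict(grid) - level
    vals = np.where(np.isfinite(vals), vals, np.nan)
    sign0 = np.sign(vals[0])
    for j in range(1, _SCAN):
        if not np.isfinite(vals[j]):
            continue
        if np.sign(vals[j]) != sign0 and np.sign(vals[j]) != 0 or vals[j] == 0.0:
            a, b = grid[j - 1], grid[j]
            try:
                return float(optimize.brentq(
                    lambda t: float(fit.predict(t)[0]) - level, a, b,
                    xtol=_XTOL))
            except ValueError:
                return float(b)
    return None


def t50_limits(fit: FitResult, topt: float | None = None,
               window: tuple[float, float] | None = None):
    """Nearest half-maximum crossings below and above the optimum.

    Returns ``(t50_min, t50_max, flags)``; a side without a crossing
    inside the search window is None and flagged.
    """
    if window is None:
        window = default_window(fit)
    if topt is None:
        topt, rmax, _ = t_opt(fit, window)
    else:
        rmax = float(fit.predict(topt)[0])
    lo, hi = _search_window(fit, window)
    half = 0.5 * rmax
    t50lo = _nearest_root(fit, half, topt, lo)
    t50hi = _nearest_root(fit, half, topt, hi)
    flags = []
    if t50lo is None:
        flags.append("no lower half-maximum crossing in window")
    if t50hi is None:
        flags.append("no upper half-maximum crossing in window")
    return t50lo, t50hi, flags


def ct_limits(fit: FitResult, topt: float | None = None,
              window: tuple[float, float] | None = None):
    """Zero crossings bounding the biokinetic range.

    Equations with fitted thermal limits (ids 13-15) return those
    parameters directly; asymptotic equations (no finite zeros) return
    ``(None, None)``.  Otherwise the nearest zero crossing on each side
    of the optimum is located numerically.
    """
    spec = fit.spec
    if "t_min" in fit.params and "t_max" in fit.params:
        return float(fit.params["t_min"]), float(fit.params["t_max"]), []
    if spec.asymptotic:
        return None, None, ["asymptotic model: thermal limits undefined"]
    if window is None:
        window = default_window(fit)
    if topt is None:
        topt, _, _ = t_opt(fit, window)
    lo, hi = window
    ctlo = _nearest_root(fit, 0.0, topt, lo)
    cthi = _nearest_root(fit, 0.0, topt, hi)
    flags = []
    if ctlo is None:
        flags.append("no lower zero crossing in window")
    if cthi is None:
        flags.append("no upper zero crossing in window")
    return ctlo, cthi, flags


def shape_stats(fit: FitResult, topt: float | None = None,
                window: tuple[float, float] | None = None):
    """Mean slope over the sub- and supra-optimal ranges, and their sum.

    activation = mean dRate/dT on (lower bound, t_opt); deactivation the
    same on (t_opt, upper bound), kept signed.  skew = activation +
    deactivation, negative exactly when the supra-optimal decline is
    steeper than the suboptimal rise.  Bounds are the thermal limits
    where defined, else the half-maximum temperatures, else the fitted
    data's extremes; the choice is reported as ``bound_source``.
    """
    if window is None:
        window = default_window(fit)
    if topt is None:
        topt, _, _ = t_opt(fit, window)
    ctlo, cthi, _ = ct_limits(fit, topt, window)
    source = "ct"
    lo, hi = ctlo, cthi
    if lo is None or hi is None:
        t50lo, t50hi, _ = t50_limits(fit, topt, window)
        lo = lo if lo is not None else t50lo
        hi = hi if hi is not None else t50hi
        source = "t50"
    if lo is None or hi is None:
        lo = lo if lo is not None else float(fit.temperatures.min())
        hi = hi if hi is not None else float(fit.temperatures.max())
        source = "data"
    flags = []
    if not (lo < topt < hi):
        flags.append("optimum at an integration bound")
        return None, None, None, source, flags
    sub = np.linspace(lo, topt, DERIV_GRID)
    sup = np.linspace(topt, hi, DERIV_GRID)
    act = float(np.nanmean(_models.derivative(fit.model_id, fit.params, sub)))
    deact = float(np.nanmean(_models.derivative(fit.model_id, fit.params, sup)))
    return act, deact, act + deact, source, flags


def cardinal_estimates(fit: FitResult,
                       window: tuple[float, float] | None = None
                       ) -> CardinalEstimates:
    """All cardinal temperatures and shape statistics for one fit."""
    if window is None:
        window = default_window(fit)
    topt, rmax, flags = t_opt(fit, window)
    t50lo, t50hi, f2 = t50_limits(fit, topt, window)
    ctlo, cthi, f3 = ct_limits(fit, topt, window)
    act, deact, skew, source, f4 = shape_stats(fit, topt, window)
    return CardinalEstimates(
        model_id=fit.model_id, t_opt=topt, r_max=rmax,
        ct_min=ctlo, ct_max=cthi, t50_min=t50lo, t50_max=t50hi,
        activation=act, deactivation=deact, skew=skew,
        bound_source=source, flags=flags + f2 + f3 + f4,
    )


_QUANTITIES = ("t_opt", "r_max", "ct_min", "ct_max", "t50_min", "t50_max",
               "activation", "deactivation", "skew")


def consensus(fits: Iterable[FitResult], weights: Mapping[int, float],
              temperatures, window: tuple[float, float] | None = None,
              estimates: Mapping[int, CardinalEstimates] | None = None
              ) -> ConsensusEstimates:
    """Akaike-weighted consensus cardinal values and per-model deviations.

    For each quantity the weighted mean runs over the models where it is
    defined, with the weights renormalized over that subset; a quantity
    defined for fewer than two models is flagged and skipped.  The rate
    deviation of each model is the mean absolute difference between its
    predicted curve and the weighted-mean curve over ``temperatures``,
    reported both in rate units and as a percentage of the consensus
    curve's maximum.
    """
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise ValueError("consensus needs at least 2 converged fits")
    T = np.asarray(temperatures, dtype=float)
    if estimates is None:
        estimates = {f.model_id: cardinal_estimates(f, window) for f in fits}

    flags = []
    wmean: dict[str, float] = {}
    devs: dict[str, dict[int, float]] = {}
    for q in _QUANTITIES:
        defined = [(f.model_id, getattr(estimates[f.model_id], q))
                   for f in fits
                   if getattr(estimates[f.model_id], q) is not None
                   and np.isfinite(getattr(estimates[f.model_id], q))]
        if len(defined) < 2:
            flags.append(f"{q}: defined for fewer than 2 models")
            continue
        w = np.array([weights.get(m, 0.0) for m, _ in defined])
        if w.sum() <= 0:
            flags.append(f"{q}: zero total weight")
            continue
        w = w / w.sum()
        vals = np.array([v for _, v in defined])
        mu = float(np.sum(w * vals))
        wmean[q] = mu
        devs[q] = {m: float(v - mu) for (m, v) in defined}

    # weighted-mean predicted curve over all converged fits
    wt = np.array([weights.get(f.model_id, 0.0) for f in fits])
    if wt.sum() <= 0:
        wt = np.ones(len(fits))
    wt = wt / wt.sum()
    preds = np.vstack([f.predict(T) for f in fits])
    consensus_curve = wt @ preds
    ref = float(np.nanmax(consensus_curve))
    rate_dev = {}
    rate_dev_pct = {}
    for f, pr in zip(fits, preds):
        d = float(np.nanmean(np.abs(pr - consensus_curve)))
        rate_dev[f.model_id] = d
        rate_dev_pct[f.model_id] = 100.0 * d / ref if ref > 0 else math.nan

    return ConsensusEstimates(
        curve_id=fits[0].curve_id,
        weighted_mean=wmean,
        deviations=devs,
        rate_deviation=rate_dev,
        rate_deviation_pct=rate_dev_pct,
        weights={f.model_id: float(w) for f, w in zip(fits, wt)},
        flags=flags,
    )
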