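"""Data-quality engines: distinguishability and sensitivity analyses.

Two simulation experiments quantify what the data must look like for
model selection and parameter estimation to be trustworthy:

1. *Distinguishability*: from each fitted equation, simulate datasets by
   adding Gaussian noise (sd = the fit's residual scale sigma-hat) to
   its predictions, refit every equation to each simulated dataset, and
   rank by BIC.  If the data are informative, each equation ranks better
   on the data it generated than on data generated by any other.

2. *Sensitivity*: degrade a curve by randomly subsampling temperatures
   or truncating to the high-rate portion of the range, refit, and
   measure the error in the optimum temperature and in the predicted
   rates relative to the full-data fit.  Critical requirements are the
   smallest designs that keep those errors inside quality thresholds
   (0.5 deg C in T_opt; 5% of the maximum rate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .cardinal import default_window, t_opt
from .data import PreparedCurve
from .fitting import FitResult, fit_all, fit_model, rank_models

__all__ = [
    "QualityThresholds",
    "CriticalRequirements",
    "simulate_from_fit",
    "distinguishability_experiment",
    "subsample_by_count",
    "truncate_by_range",
    "error_vs_quality",
    "critical_requirements",
]

logger = logging.getLogger("tpcfit")


@dataclass(frozen=True)
class QualityThresholds:
    """Minimum quality thresholds: error in the optimum temperature
    (deg C) and mean rate error (% of the maximum rate)."""

    t_opt_error_max: float = 0.5
    rate_error_max: float = 5.0

    def __post_init__(self):
        if self.t_opt_error_max <= 0 or self.rate_error_max <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class CriticalRequirements:
    critical_n_topt: int | None
    critical_n_rate: int | None
    critical_range_topt: float | None
    critical_range_rate: float | None
    flags: list


def simulate_from_fit(fit: FitResult, temperatures: Sequence[float],
                      seed: int, max_redraws: int = 100) -> PreparedCurve:
    """Simulate a noisy curve from a fitted model.

    rate_i = prediction(T_i) + eps_i with eps ~ Normal(0, sigma-hat),
    sigma-hat = sqrt(rss/n) from the fit.  Non-positive draws are
    redrawn (up to ``max_redraws`` per point) rather than clipped, since
    downstream fitting uses positive rates only and clipping would bias
    the noise scale; a point still non-positive after the budget keeps
    its last draw and is dropped by curve preparation.
    """
    T = np.asarray(temperatures, dtype=float)
    pred = fit.predict(T)
    sigma = fit.sigma
    rng = np.random.default_rng(seed)
    rates = pred + (rng.normal(0.0, sigma, size=T.size) if sigma > 0 else 0.0)
    if sigma > 0:
        for _ in range(max_redraws):
            bad = rates <= 0.0
            if not bad.any():
                break
            rates[bad] = pred[bad] + rng.normal(0.0, sigma, size=int(bad.sum()))
    keep = rates > 0.0
    return PreparedCurve(
        curve_id=f"{fit.curve_id or 'curve'}:sim:m{fit.model_id}:s{seed}",
        temperatures=T[keep], rates=np.asarray(rates)[keep],
    )


def distinguishability_experiment(curve: PreparedCurve, replicates: int = 5,
                                  seed: int = 0, fits: list | None = None
                                  ) -> pd.DataFrame:
    """Cross-simulation BIC ranking of every model on every model's data.

    For each converged fit of ``curve`` (the generator), ``replicates``
    noisy datasets are simulated and all models are refit to each and
    ranked by BIC.  Returns a tidy frame with columns ``generator_id``,
    ``fitted_id``, ``replicate``, ``bic_rank`` (NaN where a refit failed
    or was skipped).
    """
    if fits is None:
        fits = fit_all(curve, random_state=seed)
    generators = [f for f in fits if f.converged]
    skipped = [f.model_id for f in fits if not f.converged]
    if skipped:
        logger.warning("generators skipped (no converged fit): %s", skipped)
    rows = []
    ss = np.random.SeedSequence(seed)
    for gen in generators:
        child_seeds = np.random.SeedSequence([seed & 0x7FFFFFFF, gen.model_id])
        child = child_seeds.spawn(replicates)
        for rep in range(replicates):
            sim = simulate_from_fit(
                gen, curve.temperatures,
                seed=int(child[rep].generate_state(1)[0] & 0x7FFFFFFF))
            refits = fit_all(sim, random_state=seed)
            try:
                comp = rank_models(refits)
                ranks = comp.bic_rank
            except ValueError:
                ranks = {}
            for spec in _models.list_models():
                rows.append({
                    "generator_id": gen.model_id,
                    "fitted_id": spec.id,
                    "replicate": rep,
                    "bic_rank": float(ranks.get(spec.id, math.nan)),
                })
    return pd.DataFrame(rows)


def subsample_by_count(curve: PreparedCurve, n: int, seed: int,
                       keep_sides: bool = True) -> PreparedCurve:
    """Random subsample of ``n`` distinct temperatures (without
    replacement), keeping the original rate values.

    With ``keep_sides`` (default) the sample is constrained to retain at
    least one temperature on each side of the observed maximum so the
    subsampled curve stays two-sided; the constraint is logged when it
    fires.  Deterministic under ``seed``.
    """
    m = curve.n_temperatures
    if not 1 <= n <= m:
        raise ValueError(f"n={n} out of range 1..{m}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n, replace=False))
    if keep_sides and n >= 3:
        imax = int(np.argmax(curve.rates))
        lower = np.flatnonzero(np.arange(m) < imax)
        upper = np.flatnonzero(np.arange(m) > imax)
        if lower.size and not np.any(idx < imax):
            drop = rng.integers(idx.size)
            idx[drop] = rng.choice(lower)
            idx = np.sort(idx)
            logger.debug("subsample adjusted to keep a sub-optimal point")
        if upper.size and not np.any(idx > imax):
            candidates = np.flatnonzero(idx < imax)
            drop = candidates[rng.integers(candidates.size)] \
                if candidates.size else rng.integers(idx.size)
            idx[drop] = rng.choice(upper)
            idx = np.sort(idx)
            logger.debug("subsample adjusted to keep a supra-optimal point")
        idx = np.unique(idx)
    return PreparedCurve(
        curve_id=f"{curve.curve_id}:n{n}:s{seed}",
        temperatures=curve.temperatures[idx],
        rates=curve.rates[idx],
    )


def truncate_by_range(curve: PreparedCurve, range_proportion: float
                      ) -> PreparedCurve:
    """Keep the points whose rate reaches the top ``range_proportion`` of
    the observed rate scale.

    A proportion of 1.0 keeps everything (the full T_min-to-T_max
    extent); 0.5 keeps the temperatures where the rate is at least half
    the maximum.  Concretely, points with
    ``rate >= (1 - range_proportion) * max_rate`` are retained.
    """
    if not 0.0 < range_proportion <= 1.0:
        raise ValueError("range_proportion must be in (0, 1]")
    threshold = (1.0 - range_proportion) * curve.max_rate
    keep = curve.rates >= threshold
    return PreparedCurve(
        curve_id=f"{curve.curve_id}:r{range_proportion:g}",
        temperatures=curve.temperatures[keep],
        rates=curve.rates[keep],
    )


def _errors_vs_full(sub: PreparedCurve, model, full_fit: FitResult,
                    topt_full: float, window, random_state: int):
    spec = _models.get_model(model)
    if sub.n_temperatures <= spec.n_params:
        return None
    try:
        refit = fit_model(spec, sub, random_state=random_state)
    except ValueError:
        return None
    if not refit.converged:
        return None
    topt_sub, _, _ = t_opt(refit, window)
    t_err = abs(topt_sub - topt_full)
    r_max_full = float(full_fit.predict(topt_full)[0])
    diff = np.abs(refit.predict(full_fit.temperatures)
                  - full_fit.predict(full_fit.temperatures))
    rate_err = 100.0 * float(np.mean(diff)) / r_max_full
    return t_err, rate_err


def error_vs_quality(curve: PreparedCurve, model,
                     counts: Sequence[int] | None = None,
                     ranges: Sequence[float] | None = None,
                     replicates: int = 10, seed: int = 0,
                     random_state: int = 0) -> pd.DataFrame:
    """Estimation error as a function of sampling design.

    For each design point (a temperature count for random subsampling,
    or a range proportion for truncation) the model is refit and
    compared against the full-data fit: ``t_opt_error`` is the absolute
    shift of the optimum (deg C) and ``rate_error`` the mean absolute
    prediction difference over the full curve's temperatures, as % of
    the full fit's maximum rate.  Failed refits are recorded as missing.

    Default design grids: counts from n_params + 2 up to the full count,
    ranges 10%..100% in steps of 10%.
    """
    spec = _models.get_model(model)
    full_fit = fit_model(spec, curve, random_state=random_state)
    if not full_fit.converged:
        raise ValueError(f"full-data fit of model {spec.id} did not converge")
    window = default_window(full_fit)
    topt_full, _, _ = t_opt(full_fit, window)
    if counts is None:
        counts = list(range(spec.n_params + 2, curve.n_temperatures + 1))
    if ranges is None:
        ranges = [r / 10.0 for r in range(1, 11)]

    ss = np.random.SeedSequence(seed)
    rows = []
    for n in counts:
        for rep in range(replicates):
            sub_seed = int(np.random.SeedSequence(
                [seed & 0x7FFFFFFF, int(n), rep]).generate_state(1)[0]
                & 0x7FFFFFFF)
            sub = subsample_by_count(curve, int(n), seed=sub_seed)
            res = _errors_vs_full(sub, spec, full_fit, topt_full, window,
                                  random_state)
            rows.append({
                "curve_id": curve.curve_id, "model_id": spec.id,
                "design_axis": "count", "design_value": float(n),
                "replicate_seed": sub_seed,
                "t_opt_error": res[0] if res else math.nan,
                "rate_error": res[1] if res else math.nan,
            })
    for r in ranges:
        sub = truncate_by_range(curve, float(r))
        res = _errors_vs_full(sub, spec, full_fit, topt_full, window,
                              random_state)
        rows.append({
            "curve_id": curve.curve_id, "model_id": spec.id,
            "design_axis": "range", "design_value": float(r),
            "replicate_seed": -1,
            "t_opt_error": res[0] if res else math.nan,
            "rate_error": res[1] if res else math.nan,
        })
    return pd.DataFrame(rows)


def _critical_count(mean_err: pd.Series, threshold: float):
    failing = mean_err[mean_err > threshold]
    if failing.empty:
        return int(mean_err.index.min()), ["count threshold never exceeded"]
    return int(failing.index.max()) + 1, []


def _critical_range(mean_err: pd.Series, threshold: float):
    failing = mean_err[mean_err >= threshold]
    if failing.empty:
        return float(mean_err.index.min()), ["range threshold never exceeded"]
    worst = failing.index.max()
    above = [v for v in mean_err.index if v > worst]
    if not above:
        return None, ["threshold exceeded at the widest tested range"]
    return float(min(above)), []


def critical_requirements(table: pd.DataFrame,
                          thresholds: QualityThresholds | None = None
                          ) -> CriticalRequirements:
    """Critical sampling design from an error-vs-quality table.

    Per axis, replicate errors are averaged per design value.  The
    critical number of temperatures is the largest count whose mean
    error exceeds the threshold, plus one.  The critical range is the
    smallest tested range strictly wider than the largest range whose
    mean error met or exceeded the threshold (the grid granularity
    bounds the answer).  When no design value trips the threshold the
    smallest tested value is returned and flagged.
    """
    if thresholds is None:
        thresholds = QualityThresholds()
    flags: list[str] = []
    out = {"critical_n_topt": None, "critical_n_rate": None,
           "critical_range_topt": None, "critical_range_rate": None}

    counts = table[table["design_axis"] == "count"]
    if not counts.empty:
        by_n = counts.groupby("design_value")[["t_opt_error", "rate_error"]].mean()
        by_n.index = by_n.index.astype(int)
        out["critical_n_topt"], f = _critical_count(
            by_n["t_opt_error"].dropna(), thresholds.t_opt_error_max)
        flags += [f"t_opt {m}" for m in f]
        out["critical_n_rate"], f = _critical_count(
            by_n["rate_error"].dropna(), thresholds.rate_error_max)
        flags += [f"rate {m}" for m in f]

    ranges = table[table["design_axis"] == "range"]
    if not ranges.empty:
        by_r = ranges.groupby("design_value")[["t_opt_error", "rate_error"]].mean()
        out["critical_range_topt"], f = _critical_range(
            by_r["t_opt_error"].dropna(), thresholds.t_opt_error_max)
        flags += [f"t_opt {m}" for m in f]
        out["critical_range_rate"], f = _critical_range(
            by_r["rate_error"].dropna(), thresholds.rate_error_max)
        flags += [f"rate {m}" for m in f]

    return CriticalRequirements(flags=flags, **out)
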