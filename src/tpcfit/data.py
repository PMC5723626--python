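"""Reading and preparation of tidy temperature-rate tables.

Raw observations arrive as one row per (curve, temperature, replicate)
measurement.  Before fitting, replicate rates are averaged at each
temperature and only strictly positive mean rates are kept: zero or
negative rates reported beyond the thermal limits have high leverage on
asymptotic/exponential equations and degrade fits inside the biokinetic
range.  A curve qualifies for full-range fitting when it has at least
seven positive temperatures with at least two on each side of the
observed optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ResponseDataset",
    "PreparedCurve",
    "read_dataset",
    "prepare_curve",
    "qualifies_for_fitting",
    "write_prepared",
]

#: Temperatures closer than this (deg C) are treated as the same level.
TEMP_RESOLUTION = 1e-6


@dataclass
class ResponseDataset:
    """Raw replicate-level records for one response curve."""

    curve_id: str
    species: str = ""
    trait: str = "growth rate"
    rate_units: str = "day^-1"
    #: list of (temperature_C, rate, replicate_id)
    records: list = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise ValueError(f"dataset {self.curve_id!r} has no records")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["temperature", "rate", "replicate"]
        ).assign(curve_id=self.curve_id, species=self.species, trait=self.trait)


@dataclass
class PreparedCurve:
    """Replicate-averaged, positivity-filtered points for one curve,
    sorted by temperature."""

    curve_id: str
    temperatures: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.temperatures.shape != self.rates.shape:
            raise ValueError("temperatures and rates must have equal length")

    @property
    def n_temperatures(self) -> int:
        return int(self.temperatures.size)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.temperatures.tolist(), self.rates.tolist()))

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())

    @property
    def t_at_max(self) -> float:
        """Temperature of the maximum observed mean rate (ties -> lowest)."""
        return float(self.temperatures[int(np.argmax(self.rates))])


_COLUMN_ALIASES = {
    "temperature": ("temperature", "temp", "t"),
    "rate": ("rate", "growth_rate", "mu"),
    "replicate": ("replicate", "rep", "replicate_id"),
    "curve_id": ("curve_id", "curve", "id"),
    "species": ("species",),
    "trait": ("trait",),
    "rate_units": ("rate_units", "units"),
}


def _resolve(columns: Iterable[str], key: str) -> str | None:
    cols = {c.lower(): c for c in columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias in cols:
            return cols[alias]
    return None


def read_dataset(source, sep: str | None = None) -> list[ResponseDataset]:
    """Read a delimited text table into one ``ResponseDataset`` per curve.

    Parameters
    ----------
    source : path, file-like, or DataFrame
        Table with a header row.  Mandatory columns: ``temperature`` and
        ``rate`` plus either ``curve_id`` or ``species`` (+ optional
        ``trait``).  Optional: ``replicate``, ``rate_units``.
    sep : str, optional
        Field delimiter; by default comma, with tab auto-detected.

    Rows with non-numeric temperature or rate are dropped and counted in
    the per-dataset report attached as ``.n_rejected`` on the returned list.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if sep is None:
            sep = _sniff_sep(source)
        df = pd.read_csv(source, sep=sep, comment="#", encoding="utf-8")
    if df.empty:
        raise ValueError("input table is empty")

    tcol = _resolve(df.columns, "temperature")
    rcol = _resolve(df.columns, "rate")
    missing = [k for k, c in (("temperature", tcol), ("rate", rcol)) if c is None]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    ccol = _resolve(df.columns, "curve_id")
    scol = _resolve(df.columns, "species")
    if ccol is None and scol is None:
        raise ValueError("missing mandatory column(s): curve_id (or species)")
    pcol = _resolve(df.columns, "replicate")
    trcol = _resolve(df.columns, "trait")
    ucol = _resolve(df.columns, "rate_units")

    df["_temp"] = pd.to_numeric(df[tcol], errors="coerce")
    df["_rate"] = pd.to_numeric(df[rcol], errors="coerce")
    bad = df["_temp"].isna() | df["_rate"].isna() | ~np.isfinite(df["_temp"].fillna(np.nan))
    n_rejected = int(bad.sum())
    df = df[~bad]
    if df.empty:
        raise ValueError("no numeric temperature/rate rows in the table")

    if ccol is None:
        trait = df[trcol] if trcol is not None else "growth rate"
        df["_curve"] = df[scol].astype(str) + (
            ":" + df[trcol].astype(str) if trcol is not None else ""
        )
    else:
        df["_curve"] = df[ccol].astype(str)

    datasets: list[ResponseDataset] = []
    for cid, grp in df.groupby("_curve", sort=True):
        records = [
            (float(t), float(r), str(rep) if pcol is not None else "r1")
            for t, r, rep in zip(
                grp["_temp"], grp["_rate"],
                grp[pcol] if pcol is not None else ["r1"] * len(grp),
            )
        ]
        datasets.append(ResponseDataset(
            curve_id=str(cid),
            species=str(grp[scol].iloc[0]) if scol is not None else "",
            trait=str(grp[trcol].iloc[0]) if trcol is not None else "growth rate",
            rate_units=str(grp[ucol].iloc[0]) if ucol is not None else "day^-1",
            records=records,
        ))
    datasets = list(datasets)
    # attach a small read report without changing the return type contract
    for d in datasets:
        d.n_rejected_rows = n_rejected  # type: ignore[attr-defined]
    return datasets


def _sniff_sep(source) -> str:
    try:
        path = Path(source)
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        return "\t" if "\t" in first and "," not in first else ","
    except (TypeError, OSError):
        return ","


def prepare_curve(dataset: ResponseDataset | PreparedCurve) -> PreparedCurve:
    """Average replicates per temperature, then drop non-positive means.

    Averaging precedes the positivity filter, so a temperature whose
    replicates average to exactly zero is removed.  Idempotent: applying
    it to an already-prepared curve returns an equal curve.
    """
    if isinstance(dataset, PreparedCurve):
        temps, rates, cid = dataset.temperatures, dataset.rates, dataset.curve_id
        df = pd.DataFrame({"t": temps, "r": rates})
    else:
        cid = dataset.curve_id
        df = pd.DataFrame(
            [(t, r) for t, r, _ in dataset.records], columns=["t", "r"]
        )
    # collapse text-format noise in the temperature column before grouping
    df["t"] = np.round(df["t"] / TEMP_RESOLUTION) * TEMP_RESOLUTION
    mean = df.groupby("t", sort=True)["r"].mean()
    mean = mean[mean > 0.0]
    if mean.empty:
        raise ValueError(f"curve {cid!r}: no positive rates after averaging")
    return PreparedCurve(
        curve_id=cid,
        temperatures=mean.index.to_numpy(dtype=float),
        rates=mean.to_numpy(dtype=float),
    )


def qualifies_for_fitting(curve: PreparedCurve) -> tuple[bool, str]:
    """Eligibility filter for full-range fitting.

    Requires positive rates at >= 7 distinct temperatures with at least
    two temperatures strictly above and two strictly below the observed
    optimum (the temperature of the maximum mean rate; ties broken
    toward the lower temperature).
    """
    if curve.n_temperatures < 7:
        return False, "fewer than 7 temperatures"
    t_max_rate = curve.t_at_max
    n_below = int(np.sum(curve.temperatures < t_max_rate))
    n_above = int(np.sum(curve.temperatures > t_max_rate))
    if n_below < 2:
        return False, "fewer than 2 below optimum"
    if n_above < 2:
        return False, "fewer than 2 above optimum"
    return True, "ok"


def write_prepared(curves: Iterable[PreparedCurve], path, sep: str = ",") -> None:
    """Export prepared curves in the tidy input format with a mean_rate column."""
    frames = [
        pd.DataFrame({
            "curve_id": c.curve_id,
            "temperature": c.temperatures,
            "mean_rate": c.rates,
        })
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
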