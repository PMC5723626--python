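"""Ground-truth synthetic datasets and temperature grids.

The generator emulates high-resolution laboratory growth-vs-temperature
experiments: a handful of species-like curves, each measured at 18-39
individual temperatures in 0.4-0.5 deg C increments with about two
replicates per temperature, a negatively skewed unimodal true response,
and additive Gaussian measurement noise.  Per-model presets provide a
plausible unimodal parameterization for every registered equation so
that round-trip (generate -> fit -> recover) checks can run for each.

The paired present/future temperature grids are simple latitudinal
gradients with seeded noise and a uniform warming offset -- structural
stand-ins for gridded sea-surface temperature fields, adequate for
exercising the projection arithmetic but carrying no climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .data import PreparedCurve, ResponseDataset, prepare_curve

__all__ = [
    "SyntheticSpec",
    "TemperatureGrid",
    "MODEL_PRESETS",
    "PAPER_LIKE_SPECIES",
    "generate_dataset",
    "generate_curve",
    "paper_like_datasets",
    "generate_temperature_grids",
    "grid_to_frame",
    "grid_from_frame",
]

#: Default measurement noise, as a fraction of the true maximum rate.
NOISE_FRACTION = 0.05

#: Plausible unimodal parameterizations for each equation, peaking in the
#: low-to-mid 20s (deg C) at a rate of order 1 day^-1.  For the
#: thermodynamic equations these equal the registered default start
#: vectors (themselves chosen to be downward-parabola-like over 0-40 C).
MODEL_PRESETS: dict[int, dict] = {
    4: dict(_models.get_model(4).defaults),
    5: dict(_models.get_model(5).defaults),
    6: dict(_models.get_model(6).defaults),
    7: dict(_models.get_model(7).defaults),
    8: {"a": 1.0, "b": 5.0, "t_ref": 20.0},
    9: {"a": 1.0, "b": 6.0, "c": 2.5, "t_ref": 20.0},
    10: {"a": 0.2, "b": 14.0, "c": 0.0633, "t_ref": 18.0},
    11: {"a": -1.42, "b": 0.22, "c": -0.005},
    12: {"a": 0.3, "b": -0.05, "c": 0.001},
    13: {"a": 0.004, "b": 0.15, "t_min": 3.0, "t_max": 34.0},
    14: {"a": 1.2, "b": 0.15, "c": 0.4, "t_min": 2.0, "t_max": 36.0},
    15: {"r_max": 1.0, "t_min": 3.0, "t_max": 33.0, "a": 2.0, "b": 1.0},
}

#: Temperature designs on which each preset stays strictly positive
#: (start, stop); 30 evenly spaced temperatures by default.
MODEL_DESIGNS: dict[int, tuple[float, float]] = {
    4: (5.0, 32.0), 5: (5.0, 38.0), 6: (8.0, 36.0), 7: (5.0, 38.0),
    8: (5.0, 35.0), 9: (5.0, 35.0), 10: (5.0, 31.0), 11: (9.0, 35.0),
    12: (5.0, 38.0), 13: (5.0, 33.0), 14: (4.0, 35.0), 15: (4.5, 32.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic response curve."""

    generator_model_id: int
    true_params: dict
    #: (start, stop, increment) in deg C, or an explicit temperature list
    temperature_design: tuple | Sequence[float]
    replicates_per_temperature: int = 2
    noise_sd: float = 0.0
    seed: int = 0
    curve_id: str = "synthetic"
    species: str = "synthetic sp."

    def temperatures(self) -> np.ndarray:
        d = self.temperature_design
        if isinstance(d, tuple) and len(d) == 3:
            start, stop, inc = d
            if inc <= 0:
                raise ValueError("increment must be positive")
            n = int(np.floor((stop - start) / inc + 1e-9)) + 1
            return start + inc * np.arange(n)
        return np.asarray(d, dtype=float)


@dataclass
class TemperatureGrid:
    """Rectangular lon/lat grid of temperatures with a missing-data mask."""

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray  # shape (lat, lon)
    mask: np.ndarray    # True where the cell is missing

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError("values shape must be (n_lat, n_lon)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")


def generate_dataset(spec: SyntheticSpec) -> ResponseDataset:
    """Replicate-level synthetic dataset from a ground-truth model.

    rate(T, replicate) = true curve + Normal(0, noise_sd), deterministic
    under ``spec.seed``.  The ground truth is recorded on the returned
    dataset as ``.truth``.
    """
    T = spec.temperatures()
    truth = _models.evaluate(spec.generator_model_id, spec.true_params, T)
    rng = np.random.default_rng(spec.seed)
    records = []
    for rep in range(spec.replicates_per_temperature):
        noise = rng.normal(0.0, spec.noise_sd, size=T.size) \
            if spec.noise_sd > 0 else np.zeros(T.size)
        for t, r in zip(T, truth + noise):
            records.append((float(t), float(r), f"r{rep + 1}"))
    ds = ResponseDataset(
        curve_id=spec.curve_id, species=spec.species,
        trait="growth rate", rate_units="day^-1", records=records,
    )
    ds.truth = spec  # type: ignore[attr-defined]
    return ds


def generate_curve(model_id: int, n_temperatures: int = 30,
                   noise_fraction: float = 0.0, seed: int = 0,
                   replicates: int = 1, curve_id: str | None = None
                   ) -> PreparedCurve:
    """Prepared curve from a model preset on its standard design."""
    params = MODEL_PRESETS[model_id]
    lo, hi = MODEL_DESIGNS[model_id]
    T = np.linspace(lo, hi, n_temperatures)
    true_max = float(_models.evaluate(model_id, params, T).max())
    spec = SyntheticSpec(
        generator_model_id=model_id, true_params=params,
        temperature_design=list(T),
        replicates_per_temperature=replicates,
        noise_sd=noise_fraction * true_max, seed=seed,
        curve_id=curve_id or f"synthetic-m{model_id}",
    )
    return prepare_curve(generate_dataset(spec))


#: Seven species-like configurations mimicking a multi-species growth
#: experiment: all negatively skewed sine-type truths with distinct
#: optima, breadths and peak rates; designs of 18-39 temperatures at
#: 0.4-0.5 deg C steps centered (asymmetrically) on the optimum.
PAPER_LIKE_SPECIES: list[dict] = [
    {"curve_id": "sp1", "params": {"r_max": 1.10, "t_min": 2.0, "t_max": 31.0, "a": 2.0, "b": 1.0}, "n": 39, "inc": 0.4},
    {"curve_id": "sp2", "params": {"r_max": 0.80, "t_min": 5.0, "t_max": 34.0, "a": 1.8, "b": 0.9}, "n": 30, "inc": 0.5},
    {"curve_id": "sp3", "params": {"r_max": 1.40, "t_min": 0.0, "t_max": 28.0, "a": 2.2, "b": 1.1}, "n": 24, "inc": 0.5},
    {"curve_id": "sp4", "params": {"r_max": 0.60, "t_min": 8.0, "t_max": 37.0, "a": 1.6, "b": 0.8}, "n": 18, "inc": 0.5},
    {"curve_id": "sp5", "params": {"r_max": 1.00, "t_min": 3.0, "t_max": 33.0, "a": 2.0, "b": 1.0}, "n": 35, "inc": 0.4},
    {"curve_id": "sp6", "params": {"r_max": 1.25, "t_min": 4.0, "t_max": 30.0, "a": 1.9, "b": 1.2}, "n": 27, "inc": 0.45},
    {"curve_id": "sp7", "params": {"r_max": 0.90, "t_min": 6.0, "t_max": 36.0, "a": 2.1, "b": 0.9}, "n": 21, "inc": 0.5},
]


def paper_like_datasets(seed: int = 0, noise_fraction: float = NOISE_FRACTION
                        ) -> list[ResponseDataset]:
    """Seven species-like synthetic growth curves.

    Each uses the sine-type equation (id 15) with a skew parameter above
    one, so the true responses are negatively skewed (deactivation
    steeper than activation).  The temperature window covers both sides
    of the optimum, shifted one quarter of its width toward the warm
    side so the steep supra-optimal limb is sampled.
    """
    ss = np.random.SeedSequence(seed & 0x7FFFFFFF)
    children = ss.spawn(len(PAPER_LIKE_SPECIES))
    out = []
    for cfg, child in zip(PAPER_LIKE_SPECIES, children):
        p = cfg["params"]
        # optimum of the sine model: t_min + (t_max - t_min) * 2^(-1/a)
        topt = p["t_min"] + (p["t_max"] - p["t_min"]) * 0.5 ** (1.0 / p["a"])
        width = (cfg["n"] - 1) * cfg["inc"]
        start = topt - width / 2.0 + width / 4.0 * 0.5
        start = max(start, p["t_min"] + 0.5)
        if start + width > p["t_max"] - 0.2:
            start = p["t_max"] - 0.2 - width
        spec = SyntheticSpec(
            generator_model_id=15, true_params=p,
            temperature_design=(start, start + width + 1e-9, cfg["inc"]),
            replicates_per_temperature=2,
            noise_sd=noise_fraction * p["r_max"],
            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
            curve_id=cfg["curve_id"], species=cfg["curve_id"],
        )
        out.append(generate_dataset(spec))
    return out


def generate_temperature_grids(shape: tuple[int, int] = (36, 72),
                               t_equator: float = 29.0, t_pole: float = -1.0,
                               warming_offset: float = 2.0,
                               noise_sd: float = 0.5, seed: int = 0,
                               land_fraction: float = 0.25
                               ) -> tuple[TemperatureGrid, TemperatureGrid]:
    """Paired present/future temperature grids.

    The present field is a cosine latitudinal gradient from ``t_pole``
    at the poles to ``t_equator`` at the equator plus seeded Gaussian
    noise; the future field adds a uniform ``warming_offset``.  A random
    ``land_fraction`` of cells is masked identically in both grids.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    lat = np.linspace(-90.0 + 90.0 / rows, 90.0 - 90.0 / rows, rows)
    lon = np.linspace(-180.0 + 180.0 / cols, 180.0 - 180.0 / cols, cols)
    rng = np.random.default_rng(seed)
    base = t_pole + (t_equator - t_pole) * np.cos(np.deg2rad(lat))[:, None]
    present = base + rng.normal(0.0, noise_sd, size=(rows, cols))
    mask = rng.random((rows, cols)) < land_fraction
    g_now = TemperatureGrid(lon=lon, lat=lat, values=present, mask=mask)
    g_future = TemperatureGrid(lon=lon, lat=lat,
                               values=present + warming_offset,
                               mask=mask.copy())
    return g_now, g_future


_SENTINEL = -9999.0


def grid_to_frame(grid: TemperatureGrid) -> pd.DataFrame:
    """Tidy (lon, lat, temperature) table; masked cells get the sentinel
    value -9999."""
    lon2, lat2 = np.meshgrid(grid.lon, grid.lat)
    vals = np.where(grid.mask, _SENTINEL, grid.values)
    return pd.DataFrame({
        "lon": lon2.ravel(), "lat": lat2.ravel(), "temperature": vals.ravel(),
    })


def grid_from_frame(df: pd.DataFrame, value_col: str = "temperature"
                    ) -> TemperatureGrid:
    """Rebuild a rectangular grid from a tidy (lon, lat, value) table."""
    lon = np.unique(df["lon"].to_numpy(dtype=float))
    lat = np.unique(df["lat"].to_numpy(dtype=float))
    pivot = df.pivot_table(index="lat", columns="lon", values=value_col)
    vals = pivot.reindex(index=lat, columns=lon).to_numpy(dtype=float)
    mask = ~np.isfinite(vals) | (vals == _SENTINEL)
    vals = np.where(mask, np.nan, vals)
    return TemperatureGrid(lon=lon, lat=lat, values=vals, mask=mask)
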