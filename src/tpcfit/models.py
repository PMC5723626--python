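"""Registry and evaluation of full-range thermal response equations.

Twelve equations (ids 4-15) describe the unimodal dependence of a
biological rate (growth, metabolism) on temperature across the whole
biokinetic range, from classical thermodynamic "master equation" forms
to purely empirical Gaussian, polynomial and sine-based shapes.  The
registry stores, for each equation, its parameter names, a callable for
the rate, an analytic derivative where one is implemented, a default
starting vector, and the rules used to seed data-driven start values.

Temperatures are degrees Celsius throughout the public interface; the
thermodynamic equations (ids 4-7) convert to Kelvin internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "ModelSpec",
    "list_models",
    "get_model",
    "evaluate",
    "derivative",
    "initial_params",
    "registry_to_json",
]

#: Universal gas constant, J mol^-1 K^-1.  Energy-like parameters of the
#: thermodynamic equations (ids 4-7) are therefore in J mol^-1; any other
#: consistent choice of units would rescale those parameters without
#: changing the fitted curves.
GAS_CONSTANT = 8.314

CELSIUS_OFFSET = 273.15

#: Finite-difference step (deg C) for models without analytic derivatives.
FD_STEP = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """One registered temperature-response equation.

    Attributes
    ----------
    id : int
        Equation number, 4..15.
    name : str
        Short label used in tables and on the command line.
    param_names : tuple of str
        Ordered parameter symbols.
    kelvin_required : bool
        True when the formula consumes absolute temperature; the
        conversion ``T_K = T_C + 273.15`` happens inside ``evaluate``.
    asymptotic : bool
        True when the curve has no finite zero crossings, so the
        critical temperatures CTmin/CTmax are undefined.
    defaults : dict
        Default starting vector for parameters with no data analogue.
    data_driven : dict
        Maps a parameter name to one of ``max_rate``, ``mean_temp``,
        ``min_temp``, ``max_temp`` -- the curve statistic used to seed it.
    """

    id: int
    name: str
    param_names: tuple[str, ...]
    kelvin_required: bool
    asymptotic: bool
    func: Callable = field(repr=False, compare=False)
    defaults: dict = field(default_factory=dict, compare=False)
    data_driven: dict = field(default_factory=dict, compare=False)
    deriv: Callable | None = field(default=None, repr=False, compare=False)
    #: strictly positive scale parameters spanning many orders of
    #: magnitude; optimizers fit these on a log scale internally.
    log_scale: tuple[str, ...] = ()
    gas_constant: float = GAS_CONSTANT

    @property
    def n_params(self) -> int:
        return len(self.param_names)


# ---------------------------------------------------------------------------
# Equation bodies.  Each takes a temperature array (deg C) and a parameter
# mapping and returns rates; overflow is allowed to propagate as inf/nan and
# is flagged by callers rather than raised.

def _eq4(T, p):
    # Difference of two Arrhenius terms (activation minus denaturation).
    R = GAS_CONSTANT
    TK = T + CELSIUS_OFFSET
    return p["a"] * np.exp(-p["b"] / (R * TK)) - p["c"] * np.exp(-p["d"] / (R * TK))


def _eq5(T, p):
    # Arrhenius numerator over a reversible-denaturation partition term.
    R = GAS_CONSTANT
    TK = T + CELSIUS_OFFSET
    denom = 1.0 + np.exp(-p["c"] / R) * np.exp(-p["d"] / (R * TK))
    return p["a"] * TK * np.exp(-p["b"] / (R * TK)) / denom


def _eq6(T, p):
    # Master equation: active enzyme in equilibrium with low- and
    # high-temperature inactive states; a is the rate at 298.15 K.
    R = GAS_CONSTANT
    TK = T + CELSIUS_OFFSET
    num = p["a"] * (TK / 298.15) * np.exp((p["b"] / R) * (1.0 / 298.15 - 1.0 / TK))
    denom = (
        1.0
        + np.exp((p["c"] / R) * (1.0 / p["d"] - 1.0 / TK))
        + np.exp((p["e"] / R) * (1.0 / p["f"] - 1.0 / TK))
    )
    return num / denom


def _eq7(T, p):
    # Reduced master equation: high-temperature denaturation only,
    # reference temperature 293.15 K.
    R = GAS_CONSTANT
    TK = T + CELSIUS_OFFSET
    num = p["a"] * (TK / 293.15) * np.exp((p["b"] / R) * (1.0 / 293.15 - 1.0 / TK))
    denom = 1.0 + np.exp((p["c"] / R) * (1.0 / p["d"] - 1.0 / TK))
    return num / denom


def _eq8(T, p):
    # Gaussian: a is the peak rate, t_ref the optimum, b the width.
    z = (T - p["t_ref"]) / p["b"]
    return p["a"] * np.exp(-0.5 * z * z)


def _eq8_deriv(T, p):
    z = (T - p["t_ref"]) / p["b"]
    return -p["a"] * z / p["b"] * np.exp(-0.5 * z * z)


def _eq9(T, p):
    # Modified Gaussian: exponent c relaxes the quadratic decay.
    z = np.abs(T - p["t_ref"]) / p["b"]
    return p["a"] * np.exp(-0.5 * np.power(z, p["c"]))


def _eq10(T, p):
    # Exponential (Eppley-style) envelope times a quadratic window.
    z = (T - p["t_ref"]) / p["b"]
    return p["a"] * np.exp(p["c"] * T) * (1.0 - z * z)


def _eq10_deriv(T, p):
    a, b, c, tr = p["a"], p["b"], p["c"], p["t_ref"]
    z = (T - tr) / b
    return a * np.exp(c * T) * (c * (1.0 - z * z) - 2.0 * z / b)


def _eq11(T, p):
    return p["a"] + p["b"] * T + p["c"] * T * T


def _eq11_deriv(T, p):
    return p["b"] + 2.0 * p["c"] * T


def _eq12(T, p):
    # Flinn: reciprocal quadratic; never crosses zero.
    return 1.0 / (1.0 + p["a"] + p["b"] * T + p["c"] * T * T)


def _eq12_deriv(T, p):
    q = 1.0 + p["a"] + p["b"] * T + p["c"] * T * T
    return -(p["b"] + 2.0 * p["c"] * T) / (q * q)


def _eq13(T, p):
    # Ratkowsky square-root model, squared form: zero at t_min and t_max.
    g = 1.0 - np.exp(p["b"] * (T - p["t_max"]))
    return p["a"] * (T - p["t_min"]) ** 2 * g * g


def _eq13_deriv(T, p):
    a, b, tmin, tmax = p["a"], p["b"], p["t_min"], p["t_max"]
    e = np.exp(b * (T - tmax))
    g = 1.0 - e
    return 2.0 * a * (T - tmin) * g * (g - (T - tmin) * b * e)


def _eq14(T, p):
    # Kamykowski: product of two saturating exponentials, zero at the limits.
    lo = 1.0 - np.exp(-p["b"] * (T - p["t_min"]))
    hi = 1.0 - np.exp(-p["c"] * (p["t_max"] - T))
    return p["a"] * lo * hi


def _eq14_deriv(T, p):
    a, b, c, tmin, tmax = p["a"], p["b"], p["c"], p["t_min"], p["t_max"]
    eb = np.exp(-b * (T - tmin))
    ec = np.exp(-c * (tmax - T))
    return a * (b * eb * (1.0 - ec) - c * ec * (1.0 - eb))


def _eq15(T, p):
    # Modified sine: R_max at the optimum, a controls skew, b kurtosis.
    # Outside [t_min, t_max] the response is taken as zero (the fractional
    # power of a negative reduced temperature is otherwise undefined).
    T = np.asarray(T, dtype=float)
    u = (T - p["t_min"]) / (p["t_max"] - p["t_min"])
    inside = (u > 0.0) & (u < 1.0)  # exactly zero at and beyond the limits
    out = np.zeros_like(u)
    ui = u[inside]
    out[inside] = p["r_max"] * np.sin(np.pi * np.power(ui, p["a"])) ** p["b"]
    return out


# ---------------------------------------------------------------------------
# Registry.  Default start vectors for the thermodynamic equations were
# chosen so the initial curve is a downward-parabola-like response over
# 0-40 deg C peaking near 25 deg C at a rate of order one per day.

_REGISTRY: dict[int, ModelSpec] = {}


def _register(spec: ModelSpec) -> None:
    _REGISTRY[spec.id] = spec


_register(ModelSpec(
    id=4, name="hinshelwood", param_names=("a", "b", "c", "d"),
    kelvin_required=True, asymptotic=False, func=_eq4,
    defaults={"a": 2.12e5, "b": 3.0e4, "c": 1.94e34, "d": 2.0e5},
    log_scale=("a", "c"),
))
_register(ModelSpec(
    id=5, name="johnson", param_names=("a", "b", "c", "d"),
    kelvin_required=True, asymptotic=False, func=_eq5,
    defaults={"a": 717.0, "b": 3.0e4, "c": -824.7, "d": 2.5e5},
    log_scale=("a",),
))
_register(ModelSpec(
    id=6, name="heitzer", param_names=("a", "b", "c", "d", "e", "f"),
    kelvin_required=True, asymptotic=False, func=_eq6,
    defaults={"a": 1.085, "b": 5.0e4, "c": -2.0e5, "d": 283.15,
              "e": 3.5e5, "f": 303.15},
))
_register(ModelSpec(
    id=7, name="schoolfield-reduced", param_names=("a", "b", "c", "d"),
    kelvin_required=True, asymptotic=False, func=_eq7,
    defaults={"a": 0.837, "b": 5.0e4, "c": 3.0e5, "d": 302.15},
))
_register(ModelSpec(
    id=8, name="gaussian", param_names=("a", "b", "t_ref"),
    kelvin_required=False, asymptotic=True, func=_eq8, deriv=_eq8_deriv,
    defaults={"b": 5.0},
    data_driven={"a": "max_rate", "t_ref": "mean_temp"},
))
_register(ModelSpec(
    id=9, name="modified-gaussian", param_names=("a", "b", "c", "t_ref"),
    kelvin_required=False, asymptotic=True, func=_eq9,
    defaults={"b": 5.0, "c": 2.0},
    data_driven={"a": "max_rate", "t_ref": "mean_temp"},
))
_register(ModelSpec(
    id=10, name="norberg", param_names=("a", "b", "c", "t_ref"),
    kelvin_required=False, asymptotic=False, func=_eq10, deriv=_eq10_deriv,
    defaults={"b": 12.0, "c": 0.0633},
    data_driven={"a": "max_rate", "t_ref": "mean_temp"},
))
_register(ModelSpec(
    id=11, name="quadratic", param_names=("a", "b", "c"),
    kelvin_required=False, asymptotic=False, func=_eq11, deriv=_eq11_deriv,
    defaults={"a": -1.0, "b": 0.2, "c": -0.005},
))
_register(ModelSpec(
    id=12, name="flinn", param_names=("a", "b", "c"),
    kelvin_required=False, asymptotic=True, func=_eq12, deriv=_eq12_deriv,
    defaults={"a": 0.3, "b": -0.05, "c": 0.001},
))
_register(ModelSpec(
    id=13, name="ratkowsky", param_names=("a", "b", "t_min", "t_max"),
    kelvin_required=False, asymptotic=False, func=_eq13, deriv=_eq13_deriv,
    defaults={"b": 0.15},
    data_driven={"a": "max_rate", "t_min": "min_temp", "t_max": "max_temp"},
))
_register(ModelSpec(
    id=14, name="kamykowski", param_names=("a", "b", "c", "t_min", "t_max"),
    kelvin_required=False, asymptotic=False, func=_eq14, deriv=_eq14_deriv,
    defaults={"b": 0.2, "c": 0.4},
    data_driven={"a": "max_rate", "t_min": "min_temp", "t_max": "max_temp"},
))
_register(ModelSpec(
    id=15, name="boatman-sine", param_names=("r_max", "t_min", "t_max", "a", "b"),
    kelvin_required=False, asymptotic=False, func=_eq15,
    defaults={"a": 1.5, "b": 1.0},
    data_driven={"r_max": "max_rate", "t_min": "min_temp", "t_max": "max_temp"},
))


def list_models() -> list[ModelSpec]:
    """All registered equations, ordered by id (4..15)."""
    return [_REGISTRY[i] for i in sorted(_REGISTRY)]


def get_model(key: int | str | ModelSpec) -> ModelSpec:
    """Look up a model by id, name, or pass a spec through."""
    if isinstance(key, ModelSpec):
        return key
    if isinstance(key, str):
        try:
            key = int(key)
        except ValueError:
            for spec in _REGISTRY.values():
                if spec.name == key:
                    return spec
            raise KeyError(f"unknown model name: {key!r}") from None
    if key not in _REGISTRY:
        raise KeyError(f"unknown model id: {key}")
    return _REGISTRY[key]


def _check_params(model: ModelSpec, params: Mapping[str, float]) -> dict:
    missing = [n for n in model.param_names if n not in params]
    if missing:
        raise ValueError(
            f"model {model.id} ({model.name}) missing parameters: {missing}"
        )
    return {n: float(params[n]) for n in model.param_names}


def evaluate(
    model: int | str | ModelSpec,
    params: Mapping[str, float],
    temperatures: Sequence[float] | float,
) -> np.ndarray:
    """Rate at each temperature (deg C) for a model and parameter vector.

    Overflow in the exponentials yields non-finite entries rather than
    an exception; no clamping of negative rates is performed here.
    """
    spec = get_model(model)
    p = _check_params(spec, params)
    T = np.atleast_1d(np.asarray(temperatures, dtype=float))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.asarray(spec.func(T, p), dtype=float)
    return out


def derivative(
    model: int | str | ModelSpec,
    params: Mapping[str, float],
    temperature: Sequence[float] | float,
) -> np.ndarray:
    """dRate/dT (rate per deg C); analytic where implemented, otherwise a
    central finite difference with step ``FD_STEP``."""
    spec = get_model(model)
    p = _check_params(spec, params)
    T = np.atleast_1d(np.asarray(temperature, dtype=float))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if spec.deriv is not None:
            out = np.asarray(spec.deriv(T, p), dtype=float)
        else:
            h = FD_STEP
            out = (np.asarray(spec.func(T + h, p), dtype=float)
                   - np.asarray(spec.func(T - h, p), dtype=float)) / (2.0 * h)
    return out


def initial_params(model: int | str | ModelSpec, curve) -> dict[str, float]:
    """Data-driven starting vector for fitting ``model`` to ``curve``.

    Amplitude-like parameters start at the maximum observed mean rate;
    ``t_ref`` starts at the mean temperature, ``t_min``/``t_max`` at the
    observed extremes.  Parameters with no data analogue come from the
    registered per-model default vector.
    """
    spec = get_model(model)
    temps = np.asarray(curve.temperatures, dtype=float)
    rates = np.asarray(curve.rates, dtype=float)
    if temps.size == 0:
        raise ValueError("empty curve")
    stats = {
        "max_rate": float(rates.max()),
        "mean_temp": float(temps.mean()),
        "min_temp": float(temps.min()),
        "max_temp": float(temps.max()),
    }
    start: dict[str, float] = {}
    for name in spec.param_names:
        if name in spec.data_driven:
            start[name] = stats[spec.data_driven[name]]
        else:
            start[name] = float(spec.defaults[name])
    return start


def registry_to_json() -> str:
    """Human-readable JSON listing of the registry (id, name, parameters,
    defaults); consumed by the command-line ``--model`` flag handling."""
    payload = [
        {
            "id": s.id,
            "name": s.name,
            "param_names": list(s.param_names),
            "n_params": s.n_params,
            "kelvin_required": s.kelvin_required,
            "asymptotic": s.asymptotic,
            "defaults": {k: v for k, v in s.defaults.items()},
            "data_driven": dict(s.data_driven),
        }
        for s in list_models()
    ]
    return json.dumps(payload, indent=2)
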