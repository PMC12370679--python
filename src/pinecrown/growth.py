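"""Candidate secondary-branch size functions and their analytic gradients.

Nine classical growth curves relate branch size (length in cm or diameter
in mm) to the distance from the primary-branch tip to the secondary-branch
base (``SDINC``, cm):

====  ==============================  ==========================
id    form                            common name
====  ==============================  ==========================
M1    a*(1 - exp(-b*x))**c            Richards
M2    a*(1 - exp(-b*x**c))            Weibull
M3    a/(1 + b*exp(-c*x))             Logistic
M4    a/(1 + b*x**(-c))               Hossfeld
M5    a*exp(-b/x)                     Schumacher
M6    a*(1 - exp(-b*x))               Mitscherlich
M7    a*x**b*exp(-c*x)                Roeecp (unimodal)
M8    a*exp(-b*x**(-c))               Korf
M9    a*exp(-b*exp(-c*x))             Gompertz
====  ==============================  ==========================

M7 is the only curve with an interior maximum (at ``x = b/c`` for
``c > 0``); the rest increase monotonically toward an asymptote on their
admissible parameter region.

Any of the base parameters ``a``, ``b``, ``c`` can be linearly expanded in
one covariate, e.g. ``a -> a + a1*PDINC`` (length model) or
``b -> b + b1*PBD`` (diameter model); :class:`ModelSpec` records such a
map, and the derived coefficient is named by appending ``1`` to the
parameter it expands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "FUNCTIONS",
    "GrowthFunction",
    "ModelSpec",
    "evaluate",
    "gradient",
    "interior_maximum",
    "free_params",
]


@dataclass(frozen=True)
class GrowthFunction:
    """One candidate curve: closed form, gradient, and admissible box."""

    id: str
    name: str
    params: tuple[str, ...]
    value: Callable[..., np.ndarray]
    grad: Callable[..., dict[str, np.ndarray]]
    #: (lower, upper) box per parameter defining the admissible region
    bounds: Mapping[str, tuple[float, float]]
    #: True if the curve can peak strictly inside (0, inf)
    unimodal: bool = False
    #: optional cheap gradient reusing an already-computed value array
    grad_v: Callable[..., dict[str, np.ndarray]] | None = None


def _m1_value(x, a, b, c):
    return a * (1.0 - np.exp(-b * x)) ** c


def _m1_grad(x, a, b, c):
    e = np.exp(-b * x)
    u = 1.0 - e
    uc = u**c
    # log(u) -> -inf as x -> 0; guard with the limit value 0 for u == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dlogu = np.where(u > 0, np.log(np.maximum(u, 1e-300)), 0.0)
        ucm1 = np.where(u > 0, u ** (c - 1.0), 0.0)
    return {"a": uc, "b": a * c * ucm1 * x * e, "c": a * uc * dlogu}


def _m2_value(x, a, b, c):
    return a * (1.0 - np.exp(-b * x**c))


def _m2_grad(x, a, b, c):
    xc = x**c
    e = np.exp(-b * xc)
    return {"a": 1.0 - e, "b": a * xc * e, "c": a * b * xc * np.log(x) * e}


def _m3_value(x, a, b, c):
    return a / (1.0 + b * np.exp(-c * x))


def _m3_grad(x, a, b, c):
    e = np.exp(-c * x)
    d = 1.0 + b * e
    return {"a": 1.0 / d, "b": -a * e / d**2, "c": a * b * x * e / d**2}


def _m4_value(x, a, b, c):
    return a / (1.0 + b * x ** (-c))


def _m4_grad(x, a, b, c):
    xc = x ** (-c)
    d = 1.0 + b * xc
    return {"a": 1.0 / d, "b": -a * xc / d**2, "c": a * b * xc * np.log(x) / d**2}


def _m5_value(x, a, b):
    return a * np.exp(-b / x)


def _m5_grad(x, a, b):
    y = a * np.exp(-b / x)
    return {"a": y / a, "b": -y / x}


def _m6_value(x, a, b):
    return a * (1.0 - np.exp(-b * x))


def _m6_grad(x, a, b):
    e = np.exp(-b * x)
    return {"a": 1.0 - e, "b": a * x * e}


def _m7_value(x, a, b, c):
    return a * x**b * np.exp(-c * x)


def _m7_grad(x, a, b, c):
    y = a * x**b * np.exp(-c * x)
    return {"a": y / a, "b": y * np.log(x), "c": -x * y}


def _m7_grad_v(x, y, a, b, c):
    return {"a": y / a, "b": y * np.log(x), "c": -x * y}


def _m8_value(x, a, b, c):
    return a * np.exp(-b * x ** (-c))


def _m8_grad(x, a, b, c):
    xc = x ** (-c)
    y = a * np.exp(-b * xc)
    return {"a": y / a, "b": -xc * y, "c": a * b * xc * np.log(x) * np.exp(-b * xc)}


def _m9_value(x, a, b, c):
    return a * np.exp(-b * np.exp(-c * x))


def _m9_grad(x, a, b, c):
    e = np.exp(-c * x)
    y = a * np.exp(-b * e)
    return {"a": y / a, "b": -e * y, "c": b * x * e * y}


_EPS = 1e-12
_B3 = {"a": (_EPS, np.inf), "b": (_EPS, np.inf), "c": (_EPS, np.inf)}

FUNCTIONS: dict[str, GrowthFunction] = {
    f.id: f
    for f in (
        GrowthFunction("M1", "Richards", ("a", "b", "c"), _m1_value, _m1_grad, _B3),
        GrowthFunction("M2", "Weibull", ("a", "b", "c"), _m2_value, _m2_grad, _B3),
        GrowthFunction("M3", "Logistic", ("a", "b", "c"), _m3_value, _m3_grad, _B3),
        GrowthFunction("M4", "Hossfeld", ("a", "b", "c"), _m4_value, _m4_grad, _B3),
        GrowthFunction(
            "M5", "Schumacher", ("a", "b"), _m5_value, _m5_grad,
            {"a": (_EPS, np.inf), "b": (_EPS, np.inf)},
        ),
        GrowthFunction(
            "M6", "Mitscherlich", ("a", "b"), _m6_value, _m6_grad,
            {"a": (_EPS, np.inf), "b": (_EPS, np.inf)},
        ),
        GrowthFunction(
            "M7", "Roeecp", ("a", "b", "c"), _m7_value, _m7_grad,
            {"a": (_EPS, np.inf), "b": (_EPS, np.inf), "c": (0.0, np.inf)},
            unimodal=True, grad_v=_m7_grad_v,
        ),
        GrowthFunction("M8", "Korf", ("a", "b", "c"), _m8_value, _m8_grad, _B3),
        GrowthFunction("M9", "Gompertz", ("a", "b", "c"), _m9_value, _m9_grad, _B3),
    )
}


@dataclass(frozen=True)
class ModelSpec:
    """A candidate mean function plus optional covariate expansions.

    Parameters
    ----------
    function_id : str
        One of ``M1`` ... ``M9``.
    covariate_map : mapping, optional
        Maps a base parameter to the covariate column that linearly
        expands it, e.g. ``{"a": "PDINC"}`` turns ``a`` into
        ``a + a1*PDINC``. Each base parameter may carry at most one
        covariate.
    """

    function_id: str
    covariate_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.function_id not in FUNCTIONS:
            raise ValueError(f"unknown function_id {self.function_id!r}")
        base = FUNCTIONS[self.function_id].params
        object.__setattr__(self, "covariate_map", dict(self.covariate_map))
        for p in self.covariate_map:
            if p not in base:
                raise ValueError(
                    f"covariate map targets {p!r}, not a parameter of "
                    f"{self.function_id}"
                )

    @property
    def function(self) -> GrowthFunction:
        return FUNCTIONS[self.function_id]


def free_params(spec: ModelSpec) -> list[str]:
    """Ordered names of the free parameters of a spec.

    Each covariate-expanded base parameter contributes its slope right
    after itself, e.g. M7 with ``{"a": "PDINC"}`` has
    ``["a", "a1", "b", "c"]``.
    """
    names: list[str] = []
    for p in spec.function.params:
        names.append(p)
        if p in spec.covariate_map:
            names.append(p + "1")
    return names


def _effective(spec: ModelSpec, params: Mapping[str, float], covariates) -> dict:
    """Per-observation effective base parameters after covariate expansion."""
    eff = {}
    for p in spec.function.params:
        v = params[p]
        if p in spec.covariate_map:
            col = spec.covariate_map[p]
            if covariates is None or col not in covariates:
                raise ValueError(f"covariate {col!r} required by the model spec")
            v = v + params[p + "1"] * np.asarray(covariates[col], dtype=float)
        eff[p] = v
    return eff


def _check_admissible(spec: ModelSpec, params: Mapping[str, float]) -> None:
    fn = spec.function
    for p in fn.params:
        lo, hi = fn.bounds[p]
        v = params[p]
        if not np.all((np.asarray(v) >= lo - 1e-300) & (np.asarray(v) <= hi)):
            raise ValueError(
                f"parameter {p}={v} outside admissible region "
                f"[{lo}, {hi}] of {spec.function_id}"
            )


def evaluate(
    spec: ModelSpec,
    params: Mapping[str, float],
    sdinc,
    covariates=None,
    *,
    check: bool = True,
) -> np.ndarray:
    """Predicted branch size at ``sdinc`` (cm) under a candidate model.

    ``params`` holds the free parameters named by :func:`free_params`;
    ``covariates`` is any mapping (e.g. a DataFrame) providing the
    columns referenced by the spec's covariate map.
    """
    x = np.asarray(sdinc, dtype=float)
    if np.any(x <= 0):
        raise ValueError("sdinc must be strictly positive")
    if check:
        _check_admissible(spec, params)
    eff = _effective(spec, params, covariates)
    return spec.function.value(x, **eff)


def gradient(
    spec: ModelSpec,
    params: Mapping[str, float],
    sdinc,
    covariates=None,
) -> dict[str, np.ndarray]:
    """Partial derivatives of the prediction w.r.t. every free parameter.

    Covariate slopes follow by the chain rule:
    ``d/d a1 = (dY/da_eff) * covariate``.
    """
    x = np.asarray(sdinc, dtype=float)
    if np.any(x <= 0):
        raise ValueError("sdinc must be strictly positive")
    eff = _effective(spec, params, covariates)
    base_grad = spec.function.grad(x, **eff)
    out: dict[str, np.ndarray] = {}
    for p in spec.function.params:
        g = np.broadcast_to(base_grad[p], x.shape).astype(float, copy=True)
        out[p] = g
        if p in spec.covariate_map:
            cov = np.asarray(covariates[spec.covariate_map[p]], dtype=float)
            out[p + "1"] = g * cov
    return out


def interior_maximum(spec: ModelSpec, params: Mapping[str, float]) -> float | None:
    """Location (cm) of the curve's peak inside (0, inf), or ``None``.

    Only the Roeecp curve M7 is unimodal: its log-derivative
    ``b/x - c`` vanishes at ``x = b/c`` when ``c > 0``. The remaining
    candidates increase monotonically on their admissible regions, and
    M7 with ``c = 0`` grows without bound.
    """
    if not spec.function.unimodal:
        return None
    b, c = params["b"], params["c"]
    if c <= 0 or b <= 0:
        return None
    return b / c
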