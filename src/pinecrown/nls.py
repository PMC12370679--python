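"""Population-average (fixed-effects) fitting of the candidate curves.

:class:`GrowthCurveRegressor` is a scikit-learn style estimator wrapping
bounded trust-region nonlinear least squares with the analytic Jacobians
from :mod:`pinecrown.growth`. Module-level helpers cover model screening
across the nine candidates (ranked by AIC) and the exhaustive
covariate-placement search that expands curve parameters linearly in
tree- or branch-level covariates.

Conventions: Gaussian ML log-likelihood ``-n/2*(log(2*pi*RSS/n) + 1)``;
``AIC = -2*logLik + 2*(p+1)`` with the residual variance counted as a
parameter; ``RMSE = sqrt(RSS/n)``; adjusted R^2 about the response mean.
Non-convergence during screening sweeps is reported in the result table,
never raised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from pinecrown.growth import FUNCTIONS, ModelSpec, evaluate, free_params, gradient

__all__ = [
    "FitResult",
    "GrowthCurveRegressor",
    "initial_values",
    "fit",
    "screen_candidates",
    "covariate_search",
]


@dataclass
class FitResult:
    """One nonlinear least-squares fit with its evaluation indices."""

    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    n: int
    rss: float
    loglik: float
    aic: float
    mae: float
    rmse: float
    ra2: float
    converged: bool
    iterations: int
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.estimates)


def _design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame({"SDINC": arr[:, 0]})


def initial_values(spec: ModelSpec, X, y) -> dict[str, float]:
    """Heuristic starting values from exact or approximate log-linearizations.

    The Roeecp curve M7 linearizes exactly on positive responses:
    ``log y = log a + b*log x - c*x`` solved by OLS. Saturating curves
    first anchor the asymptote at 1.05*max(y) and linearize the rest.
    Covariate-expansion slopes always start at zero.
    """
    X = _design(X)
    x = np.asarray(X["SDINC"], dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty data")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate design: SDINC is constant")
    pos = y > 0
    xp, yp = x[pos], y[pos]
    if len(yp) < 3:
        raise ValueError("need at least 3 positive responses for starting values")

    def ols(A, z):
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        return coef

    fid = spec.function_id
    amax = 1.05 * float(np.max(yp))
    if fid == "M7":
        co = ols(np.column_stack([np.ones_like(xp), np.log(xp), -xp]), np.log(yp))
        init = {"a": float(np.exp(co[0])), "b": float(co[1]), "c": float(co[2])}
    elif fid == "M5":
        co = ols(np.column_stack([np.ones_like(xp), -1.0 / xp]), np.log(yp))
        init = {"a": float(np.exp(co[0])), "b": float(co[1])}
    elif fid == "M6":
        z = np.log(np.clip(1.0 - yp / amax, 1e-10, None))
        co = ols(xp[:, None], z)
        init = {"a": amax, "b": float(-co[0])}
    elif fid == "M1":
        z = np.log(np.clip(1.0 - yp / amax, 1e-10, None))
        co = ols(xp[:, None], z)
        init = {"a": amax, "b": float(-co[0]), "c": 1.0}
    elif fid == "M2":
        u = np.clip(1.0 - yp / amax, 1e-10, 1 - 1e-10)
        z = np.log(-np.log(u))
        co = ols(np.column_stack([np.ones_like(xp), np.log(xp)]), z)
        init = {"a": amax, "b": float(np.exp(co[0])), "c": float(co[1])}
    elif fid == "M3":
        z = np.log(np.clip(amax / yp - 1.0, 1e-10, None))
        co = ols(np.column_stack([np.ones_like(xp), -xp]), z)
        init = {"a": amax, "b": float(np.exp(co[0])), "c": float(co[1])}
    elif fid == "M4":
        z = np.log(np.clip(amax / yp - 1.0, 1e-10, None))
        co = ols(np.column_stack([np.ones_like(xp), -np.log(xp)]), z)
        init = {"a": amax, "b": float(np.exp(co[0])), "c": float(co[1])}
    elif fid == "M8":
        co = ols(np.column_stack([np.ones_like(xp), -1.0 / xp]), np.log(yp))
        init = {"a": float(np.exp(co[0])), "b": float(co[1]), "c": 1.0}
    elif fid == "M9":
        u = np.clip(yp / amax, 1e-10, 1 - 1e-10)
        z = np.log(-np.log(u))
        co = ols(np.column_stack([np.ones_like(xp), -xp]), z)
        init = {"a": amax, "b": float(np.exp(co[0])), "c": float(co[1])}
    else:  # pragma: no cover
        raise ValueError(f"unknown function_id {fid!r}")

    # clip into the admissible box and zero-start covariate slopes
    for p, (lo, hi) in spec.function.bounds.items():
        init[p] = float(np.clip(init[p], max(lo, 1e-8), min(hi, 1e12)))
    for p in spec.covariate_map:
        init[p + "1"] = 0.0
    return {p: init[p] for p in free_params(spec)}


class GrowthCurveRegressor(BaseEstimator, RegressorMixin):
    """Bounded NLS fit of one candidate branch-size curve.

    Parameters
    ----------
    spec : ModelSpec
        Candidate curve and optional covariate expansions.
    init : dict, optional
        Starting values; computed by :func:`initial_values` when omitted.
    max_iter : int
        Maximum trust-region iterations (function evaluations cap).
    xtol : float
        Relative optimizer tolerance.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict of the estimated free parameters
    result_ : :class:`FitResult` with SEs, p-values and fit indices
    converged_ : bool
    """

    def __init__(self, spec: ModelSpec | None = None, init: dict | None = None,
                 max_iter: int = 500, xtol: float = 1e-10):
        self.spec = spec
        self.init = init
        self.max_iter = max_iter
        self.xtol = xtol

    def fit(self, X, y):
        spec = self.spec if self.spec is not None else ModelSpec("M7")
        Xd = _design(X)
        y = np.asarray(y, dtype=float)
        if len(Xd) != len(y):
            raise ValueError("X and y length mismatch")
        names = free_params(spec)
        p = len(names)
        n = len(y)
        if n <= p:
            self.result_ = _flagged_result(spec, names, n,
                                           "under-identified: n <= n_params")
            self.params_, self.converged_ = self.result_.estimates, False
            return self

        init = dict(self.init) if self.init is not None else initial_values(spec, Xd, y)
        x0 = np.array([init[nm] for nm in names], dtype=float)
        lo = np.array([spec.function.bounds.get(nm, (-np.inf, np.inf))[0]
                       for nm in names])
        hi = np.array([spec.function.bounds.get(nm, (-np.inf, np.inf))[1]
                       for nm in names])
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, hi))

        def unpack(v):
            return dict(zip(names, v))

        def resid(v):
            with np.errstate(all="ignore"):
                r = evaluate(spec, unpack(v), Xd["SDINC"], Xd, check=False) - y
            return np.where(np.isfinite(r), r, 1e10)

        def jac(v):
            with np.errstate(all="ignore"):
                g = gradient(spec, unpack(v), Xd["SDINC"], Xd)
            J = np.column_stack([g[nm] for nm in names])
            return np.where(np.isfinite(J), J, 0.0)

        try:
            sol = optimize.least_squares(
                resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=self.xtol, ftol=self.xtol, gtol=1e-12,
                max_nfev=self.max_iter,
            )
        except Exception as exc:  # noqa: BLE001 - screening must not crash
            self.result_ = _flagged_result(spec, names, n, f"optimizer error: {exc}")
            self.params_, self.converged_ = self.result_.estimates, False
            return self

        est = unpack(sol.x)
        r = resid(sol.x)
        rss = float(r @ r)
        J = jac(sol.x)
        converged = bool(sol.status > 0) and np.isfinite(rss)
        se, pv = {}, {}
        dof = n - p
        s2 = rss / dof
        JtJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JtJ)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
            tstat = sol.x / np.where(sd > 0, sd, np.inf)
            pvals = 2 * stats.t.sf(np.abs(tstat), dof)
            se = dict(zip(names, sd))
            pv = dict(zip(names, pvals))
        except np.linalg.LinAlgError:
            converged = False
            se = {nm: np.nan for nm in names}
            pv = {nm: np.nan for nm in names}

        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1 - rss / sst if sst > 0 else np.nan
        ra2 = 1 - (1 - r2) * (n - 1) / (n - p - 1)
        self.result_ = FitResult(
            spec=spec, estimates=est, se=se, pvalues=pv, n=n, rss=rss,
            loglik=float(loglik), aic=float(-2 * loglik + 2 * (p + 1)),
            mae=float(np.mean(np.abs(r))), rmse=float(np.sqrt(rss / n)),
            ra2=float(ra2), converged=converged, iterations=int(sol.nfev),
            message=sol.message,
        )
        self.params_ = est
        self.converged_ = converged
        self.n_features_in_ = Xd.shape[1]
        return self

    def predict(self, X):
        Xd = _design(X)
        spec = self.result_.spec
        return evaluate(spec, self.params_, Xd["SDINC"], Xd, check=False)


def _flagged_result(spec, names, n, message) -> FitResult:
    nanmap = {nm: np.nan for nm in names}
    return FitResult(spec=spec, estimates=nanmap, se=dict(nanmap),
                     pvalues=dict(nanmap), n=n, rss=np.nan, loglik=np.nan,
                     aic=np.nan, mae=np.nan, rmse=np.nan, ra2=np.nan,
                     converged=False, iterations=0, message=message)


def fit(spec: ModelSpec, data: pd.DataFrame, response: str = "SBL",
        init: dict | None = None, **kw) -> FitResult:
    """Fit one candidate model to a flat branch table; never raises on
    non-convergence (the result carries the flag)."""
    est = GrowthCurveRegressor(spec=spec, init=init, **kw)
    try:
        est.fit(data, data[response])
    except ValueError as exc:
        return _flagged_result(spec, free_params(spec), len(data), str(exc))
    return est.result_


def screen_candidates(data: pd.DataFrame, function_ids: Sequence[str] | None = None,
                      response: str = "SBL") -> pd.DataFrame:
    """Fit every candidate curve and rank by AIC (ascending).

    Non-convergent candidates are retained with ``converged=False`` and
    sort last, mirroring the dashed entries of a screening table.
    """
    if function_ids is None:
        function_ids = list(FUNCTIONS)
    if len(function_ids) == 0:
        raise ValueError("empty candidate list")
    rows = []
    for fid in function_ids:
        res = fit(ModelSpec(fid), data, response=response)
        rows.append({
            "function_id": fid, "name": FUNCTIONS[fid].name,
            "aic": res.aic, "loglik": res.loglik, "rmse": res.rmse,
            "mae": res.mae, "ra2": res.ra2, "converged": res.converged,
            "result": res,
        })
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["converged", "aic"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return table


def covariate_search(base_spec: ModelSpec, data: pd.DataFrame,
                     candidate_covariates: Sequence[str], response: str = "SBL",
                     alpha: float = 0.05, max_terms: int = 1) -> pd.DataFrame:
    """Exhaustive linear covariate-placement search on the base curve.

    Each base parameter (a, b, c) may be expanded by at most one
    candidate covariate; all placements with up to ``max_terms`` total
    expansions are fitted. Expansions whose added slope is not
    significant at ``alpha`` are rejected. Survivors (always including
    the base model) are ranked by AIC.
    """
    for cov in candidate_covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} not in data")
    base_params = base_spec.function.params
    options: list[list[tuple[str, str] | None]] = [
        [None] + [(p, c) for c in candidate_covariates] for p in base_params
    ]
    rows = []
    for combo in itertools.product(*options):
        placed = [pc for pc in combo if pc is not None]
        if len(placed) > max_terms:
            continue
        cmap = dict(base_spec.covariate_map)
        cmap.update(dict(placed))
        spec = ModelSpec(base_spec.function_id, cmap)
        res = fit(spec, data, response=response)
        added = [p + "1" for p, _ in placed]
        significant = res.converged and all(
            np.isfinite(res.pvalues.get(nm, np.nan))
            and res.pvalues[nm] < alpha for nm in added
        )
        rows.append({
            "covariate_map": cmap, "n_terms": len(placed), "aic": res.aic,
            "ra2": res.ra2, "rmse": res.rmse, "converged": res.converged,
            "significant": bool(significant) if placed else res.converged,
            "result": res,
        })
    table = pd.DataFrame(rows)
    survivors = table[table["significant"]].copy()
    if survivors.empty:
        survivors = table[table["n_terms"] == 0].copy()
    return survivors.sort_values("aic", na_position="last").reset_index(drop=True)
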