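"""Two-level nonlinear mixed-effects estimation for branch-size curves.

The observation model is

    y_ijk = f(phi_ijk, v_ijk) + e_ijk,        e_ijk ~ N(0, R_ij)
    phi_ijk = beta + B_ijk b_i + M_ijk b_ij,  b_i ~ N(0, D1), b_ij ~ N(0, D2)

with ``i`` indexing primary branches, ``j`` whorls of secondary branches
nested in branch ``i``, and ``k`` the observations within a whorl. The
random effects perturb a chosen subset of the curve parameters at each
level (:class:`RandomEffectsSpec`); ``R_ij`` defaults to sigma2*I but can
carry a power or exponential variance function and an AR(1)/MA(1)/
ARMA(1,1) within-whorl correlation (:class:`VarianceSpec`).

Estimation is maximum likelihood by a Lindstrom-Bates style alternating
algorithm: (1) conditional modes of all random effects by penalized
Gauss-Newton (posterior-mean updates of the model linearized in the
effects); (2) given the linearization at the modes, the variance
parameters are estimated by profiled ML of the working linear mixed
model, with the fixed effects and sigma2 profiled out in closed form.
D1 and D2 are parameterized through their log-Cholesky factors relative
to sigma2, so they stay positive semidefinite. The reported
log-likelihood is the Laplace-approximate marginal likelihood evaluated
at the conditional modes; it coincides with adaptive quadrature whenever
f is linear in the random effects.

The whole likelihood is evaluated without Python-level loops over
groups: whorl blocks are padded into a batched array, inverted with
stacked linear algebra, and the primary-branch level is folded in by a
blockwise Woodbury identity with segment sums.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from pinecrown.growth import ModelSpec, evaluate, free_params, gradient
from pinecrown import nls as _nls

__all__ = [
    "RandomEffectsSpec",
    "VarianceSpec",
    "NLMEResult",
    "TwoLevelNLME",
    "fit_nlme",
    "loglik",
    "lrt",
    "search_random_effects",
    "predict",
]

GROUP_COLS = ("tree_id", "branch_id")
WHORL_COL = "whorl_id"


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which curve parameters receive random perturbations at each level."""

    level1_params: tuple[str, ...] = ()
    level2_params: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "level1_params", tuple(self.level1_params))
        object.__setattr__(self, "level2_params", tuple(self.level2_params))
        total = len(self.level1_params) + len(self.level2_params)
        if total > 4:
            warnings.warn(
                f"{total} random-effect parameters requested; fits with more "
                "than four rarely converge on branch data", stacklevel=2)

    @property
    def q1(self) -> int:
        return len(self.level1_params)

    @property
    def q2(self) -> int:
        return len(self.level2_params)


@dataclass(frozen=True)
class VarianceSpec:
    """Within-whorl residual structure R_ij = sigma2 * G^0.5 Gamma G^0.5.

    ``within_group``: 'constant', 'power' (sd ~ |mu|^delta) or
    'exponential' (sd ~ exp(delta*mu)); ``correlation``: 'independent',
    'AR1', 'MA1' or 'ARMA11' over the within-whorl observation order.
    """

    within_group: str = "constant"
    correlation: str = "independent"

    def __post_init__(self):
        if self.within_group not in ("constant", "power", "exponential"):
            raise ValueError(f"unknown variance function {self.within_group!r}")
        if self.correlation not in ("independent", "AR1", "MA1", "ARMA11"):
            raise ValueError(f"unknown correlation {self.correlation!r}")

    @property
    def n_var_params(self) -> int:
        return int(self.within_group != "constant")

    @property
    def n_cor_params(self) -> int:
        return {"independent": 0, "AR1": 1, "MA1": 1, "ARMA11": 2}[self.correlation]


@dataclass
class NLMEResult:
    """ML fit of the two-level model: estimates, EBLUPs and fit indices."""

    spec: ModelSpec
    re_spec: RandomEffectsSpec
    var_spec: VarianceSpec
    beta: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    D1: pd.DataFrame
    D2: pd.DataFrame
    sigma2: float
    var_params: dict[str, float]
    loglik: float
    aic: float
    n: int
    n_params: int
    eblups_level1: pd.DataFrame
    eblups_level2: pd.DataFrame
    mae: float
    rmse: float
    ra2: float
    converged: bool
    iterations: int
    message: str = ""

    def variance_report(self) -> dict[str, float]:
        """Variance components as printed in study tables: variances per
        random parameter plus the level-1 correlation(s)."""
        out = {"sigma2": self.sigma2}
        for p in self.re_spec.level1_params:
            out[f"var_{p}_level1"] = float(self.D1.loc[p, p])
        for pa, pb in itertools.combinations(self.re_spec.level1_params, 2):
            denom = np.sqrt(self.D1.loc[pa, pa] * self.D1.loc[pb, pb])
            out[f"corr_{pa}{pb}_level1"] = (
                float(self.D1.loc[pa, pb] / denom) if denom > 0 else 0.0)
        for p in self.re_spec.level2_params:
            out[f"var_{p}_level2"] = float(self.D2.loc[p, p])
        return out


# --------------------------------------------------------------------------
# workspace: data layout and padded whorl blocks
# --------------------------------------------------------------------------

class _Workspace:
    """Sorted observation arrays plus the whorl padding index."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 re_spec: RandomEffectsSpec, response: str):
        df = data.sort_values(list(GROUP_COLS) + [WHORL_COL],
                              kind="stable").reset_index(drop=True)
        self.df = df
        self.y = df[response].to_numpy(dtype=float)
        self.x = df["SDINC"].to_numpy(dtype=float)
        self.n = len(df)
        self.spec = spec
        self.re_spec = re_spec
        self.names = free_params(spec)
        for p in re_spec.level1_params + re_spec.level2_params:
            if p not in self.names:
                raise ValueError(f"random-effect parameter {p!r} is not a "
                                 f"free parameter of the model spec")

        g1_codes, self.g1_keys = pd.factorize(
            pd.MultiIndex.from_frame(df[list(GROUP_COLS)]))
        g2_codes, self.g2_keys = pd.factorize(
            pd.MultiIndex.from_frame(df[list(GROUP_COLS) + [WHORL_COL]]))
        self.obs_g1 = g1_codes
        self.obs_g2 = g2_codes
        self.G = int(g1_codes.max()) + 1
        self.W = int(g2_codes.max()) + 1
        # group of each whorl
        first = np.zeros(self.W, dtype=int)
        first[g2_codes[::-1]] = np.arange(self.n)[::-1]
        self.whorl_g1 = g1_codes[first]

        counts = np.bincount(g2_codes, minlength=self.W)
        self.m = int(counts.max())
        self.counts = counts
        # padding index: obs are sorted, so each whorl is a contiguous run
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.pad_idx = np.minimum(
            starts[:, None] + np.arange(self.m)[None, :],
            np.concatenate([[0], np.cumsum(counts)])[1:, None] - 1,
        )
        self.mask = np.arange(self.m)[None, :] < counts[:, None]
        # within-whorl observation order (for correlation structures)
        self.pos = np.arange(self.n) - starts[g2_codes]
        self.lags = np.abs(np.arange(self.m)[:, None] - np.arange(self.m)[None, :])
        self.whorl_starts = starts
        gcounts = np.bincount(g1_codes, minlength=self.G)
        self.group_starts = np.concatenate([[0], np.cumsum(gcounts)[:-1]])

    def pad(self, arr: np.ndarray) -> np.ndarray:
        """(n,...) -> (W, m, ...) with zeros outside the mask."""
        out = arr[self.pad_idx]
        if out.ndim == 2:
            return out * self.mask
        return out * self.mask[..., None]

    def mean(self, beta: Mapping[str, float], u1, u2) -> np.ndarray:
        """Conditional mean only (no gradients)."""
        params = {}
        for p in self.names:
            v = np.full(self.n, beta[p])
            if u1 is not None and p in self.re_spec.level1_params:
                v = v + u1[self.obs_g1, self.re_spec.level1_params.index(p)]
            if u2 is not None and p in self.re_spec.level2_params:
                v = v + u2[self.obs_g2, self.re_spec.level2_params.index(p)]
            params[p] = v
        with np.errstate(all="ignore"):
            return evaluate(self.spec, params, self.x, self.df, check=False)

    def curve(self, beta: Mapping[str, float], u1: np.ndarray | None,
              u2: np.ndarray | None):
        """Per-observation mean and parameter gradients at beta + effects.

        ``u1``: (G, q1) level-1 effects; ``u2``: (W, q2) level-2 effects.
        Returns (mu, X (n,p), Z1 (n,q1), Z2 (n,q2)).
        """
        params = {}
        for idx, p in enumerate(self.names):
            v = np.full(self.n, beta[p])
            if u1 is not None and p in self.re_spec.level1_params:
                v = v + u1[self.obs_g1, self.re_spec.level1_params.index(p)]
            if u2 is not None and p in self.re_spec.level2_params:
                v = v + u2[self.obs_g2, self.re_spec.level2_params.index(p)]
            params[p] = v
        with np.errstate(all="ignore"):
            mu = evaluate(self.spec, params, self.x, self.df, check=False)
            g = gradient(self.spec, params, self.x, self.df)
        X = np.column_stack([g[p] for p in self.names])
        Z1 = (np.column_stack([g[p] for p in self.re_spec.level1_params])
              if self.re_spec.q1 else np.zeros((self.n, 0)))
        Z2 = (np.column_stack([g[p] for p in self.re_spec.level2_params])
              if self.re_spec.q2 else np.zeros((self.n, 0)))
        return mu, X, Z1, Z2


# --------------------------------------------------------------------------
# theta parameterization
# --------------------------------------------------------------------------

def _chol_unpack(theta: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky vector -> lower factor L with exp'ed diagonal."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                # diagonal capped: random effects perturb O(1) curve
                # parameters, so relative SDs above ~e^3 are nonsense
                L[i, j] = np.exp(np.clip(theta[k], -30, 3))
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def _chol_pack(D: np.ndarray) -> np.ndarray:
    q = D.shape[0]
    L = np.linalg.cholesky(D + 1e-12 * np.trace(D + np.eye(q)) / q * np.eye(q))
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def _n_theta(re_spec: RandomEffectsSpec, var_spec: VarianceSpec) -> int:
    q1, q2 = re_spec.q1, re_spec.q2
    return (q1 * (q1 + 1)) // 2 + (q2 * (q2 + 1)) // 2 \
        + var_spec.n_var_params + var_spec.n_cor_params


def _split_theta(theta, re_spec, var_spec):
    q1, q2 = re_spec.q1, re_spec.q2
    n1, n2 = (q1 * (q1 + 1)) // 2, (q2 * (q2 + 1)) // 2
    L1 = _chol_unpack(theta[:n1], q1)
    L2 = _chol_unpack(theta[n1:n1 + n2], q2)
    rest = theta[n1 + n2:]
    delta = rest[0] if var_spec.n_var_params else 0.0
    cor = rest[var_spec.n_var_params:]
    return L1 @ L1.T, L2 @ L2.T, delta, cor


def _correlation_matrix(var_spec: VarianceSpec, lags: np.ndarray, cor) -> np.ndarray:
    if var_spec.correlation == "independent":
        return np.eye(lags.shape[0])
    if var_spec.correlation == "AR1":
        rho = np.tanh(cor[0])
        return rho ** lags
    if var_spec.correlation == "MA1":
        t1 = cor[0]
        r1 = t1 / (1.0 + t1 * t1)
        return np.where(lags == 0, 1.0, np.where(lags == 1, r1, 0.0))
    # ARMA(1,1)
    phi, t1 = np.tanh(cor[0]), cor[1]
    r1 = (1 + phi * t1) * (phi + t1) / (1 + 2 * phi * t1 + t1 * t1)
    out = np.where(lags == 0, 1.0, r1 * phi ** np.maximum(lags - 1, 0))
    return out


def _variance_weights(var_spec: VarianceSpec, mu: np.ndarray, delta) -> np.ndarray:
    """Standard-deviation weights g_k of the variance function."""
    if var_spec.within_group == "constant":
        return np.ones_like(mu)
    if var_spec.within_group == "power":
        return np.abs(mu) ** delta + 1e-8
    return np.exp(np.clip(delta * mu, -40, 40))


# --------------------------------------------------------------------------
# core batched linear algebra
# --------------------------------------------------------------------------

def _segsum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum contiguous segments of arr (segment starts given) along axis 0."""
    return np.add.reduceat(arr, starts, axis=0)


class _MarginalDiag:
    """V* with diagonal within-whorl errors, by blockwise Woodbury.

    Lambda_j = diag(g^2) + U2 D2* U2' is inverted through its q2 x q2
    capacitance per whorl; the primary-branch level is folded in through
    the q1 x q1 information M_i = D1*^{-1} + Z1' Lambda^{-1} Z1 per
    group. Everything runs on observation-level arrays with contiguous
    segment sums — no padded blocks.
    """

    def __init__(self, ws: _Workspace, Z1, Z2, D1s, D2s, g):
        self.ws = ws
        self.q1, self.q2 = Z1.shape[1], Z2.shape[1]
        self.c = g * g  # diagonal of C
        self.Z2 = Z2
        logdet = float(np.sum(np.log(self.c)))
        if self.q2:
            D2inv = np.linalg.inv(D2s + 1e-14 * np.eye(self.q2))
            Uc = Z2 / self.c[:, None]
            B = _segsum(Z2[:, :, None] * Uc[:, None, :], ws.whorl_starts)
            B += D2inv[None]
            sign, ld = np.linalg.slogdet(B)
            s2_, ld2 = np.linalg.slogdet(D2s + 1e-14 * np.eye(self.q2))
            if np.any(sign <= 0):
                raise np.linalg.LinAlgError("whorl capacitance not PD")
            self.Binv = np.linalg.inv(B)
            logdet += float(ld.sum()) + ws.W * float(ld2)
        self.logdet_lambda = logdet
        self.D1s, self.D2s = D1s, D2s
        if self.q1:
            self.Lz1 = self.lam_solve(Z1)
            Mi = _segsum(Z1[:, :, None] * self.Lz1[:, None, :], ws.group_starts)
            D1inv = np.linalg.inv(D1s + 1e-14 * np.eye(self.q1))
            Mi += D1inv[None]
            self.Mi = Mi
            self.Z1 = Z1
            sign, ld = np.linalg.slogdet(Mi)
            s1_, ld1 = np.linalg.slogdet(D1s + 1e-14 * np.eye(self.q1))
            if np.any(sign <= 0):
                raise np.linalg.LinAlgError("level-1 information not PD")
            self.logdet = logdet + float(ld.sum()) + ws.G * float(ld1)
        else:
            self.Mi = None
            self.logdet = logdet

    def lam_solve(self, R: np.ndarray) -> np.ndarray:
        """Lambda^{-1} R for observation-level columns R (n, r)."""
        t = R / self.c[:, None]
        if self.q2:
            s = _segsum(self.Z2[:, :, None] * t[:, None, :], self.ws.whorl_starts)
            Bs = self.Binv @ s
            t = t - np.einsum("nq,nqr->nr", self.Z2 / self.c[:, None],
                              Bs[self.ws.obs_g2])
        return t

    def inner(self, R: np.ndarray) -> np.ndarray:
        LR = self.lam_solve(R)
        K = R.T @ LR
        if self.q1:
            Q = _segsum(self.Z1[:, :, None] * LR[:, None, :], self.ws.group_starts)
            MiQ = np.linalg.solve(self.Mi, Q)
            K = K - np.einsum("gqr,gqs->rs", Q, MiQ)
        return K

    def blup(self, e: np.ndarray):
        ws = self.ws
        Le = self.lam_solve(e[:, None])[:, 0]
        if self.q1:
            q = _segsum(self.Z1 * Le[:, None], ws.group_starts)
            b1 = np.linalg.solve(self.Mi, q[..., None])[..., 0]
            ve = Le - np.einsum("nq,nq->n", self.Lz1, b1[ws.obs_g1])
        else:
            b1 = np.zeros((ws.G, 0))
            ve = Le
        if self.q2:
            b2 = _segsum(self.Z2 * ve[:, None], ws.whorl_starts) @ self.D2s.T
        else:
            b2 = np.zeros((ws.W, 0))
        return b1, b2


class _MarginalDense:
    """V* with correlated within-whorl errors via padded whorl blocks.

    Used when an AR(1)/MA(1)/ARMA(1,1) structure is active; whorl blocks
    Lambda_j = G^0.5 Gamma G^0.5 + U2 D2* U2' are inverted as a batch.
    """

    def __init__(self, ws: _Workspace, Z1, Z2, D1s, D2s, g, Gamma_lags):
        W, m = ws.W, ws.m
        self.ws = ws
        self.q1 = Z1.shape[1]
        gp = ws.pad(g)
        C = gp[:, :, None] * gp[:, None, :] * Gamma_lags[None, :, :]
        offmask = ws.mask[:, :, None] & ws.mask[:, None, :]
        C = np.where(offmask, C, 0.0)
        # unit diagonal on padded slots keeps determinants/inverses clean
        dpad = ~ws.mask
        C[:, np.arange(m), np.arange(m)] += dpad
        if Z2.shape[1]:
            U2 = ws.pad(Z2)
            C = C + np.einsum("wmq,qr,wnr->wmn", U2, D2s, U2)
            self.U2 = U2
        else:
            self.U2 = None
        self.A = np.linalg.inv(C)
        sign, ld = np.linalg.slogdet(C)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("whorl block not positive definite")
        self.logdet_lambda = float(ld.sum())
        self.D1s, self.D2s = D1s, D2s
        if self.q1:
            self.U1 = ws.pad(Z1)
            self.AU1 = self.A @ self.U1
            # M_i = D1*^{-1} + sum_j U1' A U1
            UAU = np.einsum("wmq,wmr->wqr", self.U1, self.AU1)
            Mi = np.zeros((ws.G, self.q1, self.q1))
            np.add.at(Mi, ws.whorl_g1, UAU)
            D1inv = np.linalg.inv(D1s + 1e-14 * np.eye(self.q1))
            Mi += D1inv[None]
            self.Mi = Mi
            sign, ld = np.linalg.slogdet(Mi)
            s2, ld2 = np.linalg.slogdet(D1s + 1e-14 * np.eye(self.q1))
            if np.any(sign <= 0):
                raise np.linalg.LinAlgError("level-1 information not PD")
            self.logdet = self.logdet_lambda + float(ld.sum()) + ws.G * float(ld2)
        else:
            self.Mi = None
            self.logdet = self.logdet_lambda

    def inner(self, R: np.ndarray) -> np.ndarray:
        """R' V*^{-1} R for column-stacked R (n, r)."""
        Rp = self.ws.pad(R)
        AR = self.A @ Rp
        K = np.einsum("wmr,wms->rs", Rp, AR)
        if self.q1:
            Q = np.zeros((self.ws.G, self.q1, R.shape[1]))
            np.add.at(Q, self.ws.whorl_g1, np.einsum("wmq,wmr->wqr", self.U1, AR))
            MiQ = np.linalg.solve(self.Mi, Q)
            K = K - np.einsum("gqr,gqs->rs", Q, MiQ)
        return K

    def blup(self, e: np.ndarray):
        """Conditional modes (b_i, b_ij) of the linearized model for
        residual vector e = w - X beta."""
        ws = self.ws
        ep = ws.pad(e)
        Ae = self.A @ ep[..., None]
        if self.q1:
            q = np.zeros((ws.G, self.q1))
            np.add.at(q, ws.whorl_g1,
                      np.einsum("wmq,wm->wq", self.U1, Ae[..., 0]))
            b1 = np.linalg.solve(self.Mi, q[..., None])[..., 0]
            ve = Ae[..., 0] - np.einsum("wmq,wq->wm", self.AU1, b1[ws.whorl_g1])
        else:
            b1 = np.zeros((ws.G, 0))
            ve = Ae[..., 0]
        if self.U2 is not None:
            b2 = np.einsum("qr,wmr,wm->wq", self.D2s, self.U2, ve)
        else:
            b2 = np.zeros((ws.W, 0))
        return b1, b2


def _curve_nodes(ws, beta, u1_nodes, u2_nodes):
    """Mean and level-2 gradients for a batch of level-1 node values.

    ``u1_nodes``: (K, G, q1); ``u2_nodes``: (K, W, q2) or None. Uses the
    broadcasting of the curve formulas to evaluate all K quadrature
    nodes in one vectorized pass; returns mu (K, n) and Z2 (K, n, q2).
    """
    re_spec = ws.re_spec
    K = u1_nodes.shape[0]
    params = {}
    for p in ws.names:
        v = np.broadcast_to(np.float64(beta[p]), (K, ws.n))
        if p in re_spec.level1_params:
            v = v + u1_nodes[:, ws.obs_g1, re_spec.level1_params.index(p)]
        if u2_nodes is not None and p in re_spec.level2_params:
            v = v + u2_nodes[:, ws.obs_g2, re_spec.level2_params.index(p)]
        params[p] = v
    fn = ws.spec.function
    eff = {}
    covmap = ws.spec.covariate_map
    for p in fn.params:
        e = params[p]
        if p in covmap:
            e = e + params[p + "1"] * ws.df[covmap[p]].to_numpy(dtype=float)
        eff[p] = e
    with np.errstate(all="ignore"):
        mu = fn.value(ws.x, **eff)
        if re_spec.q2:
            base_grad = (fn.grad_v(ws.x, mu, **eff) if fn.grad_v is not None
                         else fn.grad(ws.x, **eff))
        else:
            base_grad = None
    Z2 = None
    if re_spec.q2:
        cols = []
        for p in re_spec.level2_params:
            if p.endswith("1") and p[:-1] in covmap:
                g = base_grad[p[:-1]] * ws.df[covmap[p[:-1]]].to_numpy(dtype=float)
            else:
                g = base_grad[p]
            cols.append(np.broadcast_to(g, (K, ws.n)))
        Z2 = np.stack(cols, axis=2)
    return mu, Z2


def _agq_refine(ws, var_spec, beta, theta, s2, u1, u2, n_nodes=None,
                recenter=2, maxiter=250):
    """Adaptive Gauss-Hermite refinement of the fixed effects.

    The linearization (Laplace) step biases the fixed effects when
    random effects enter the curve strongly nonlinearly (an exponent
    perturbation integrated over a wide within-group size range). This
    stage re-maximizes, over beta only, the marginal likelihood with the
    level-1 effects integrated by adaptive Gauss-Hermite quadrature
    centered at the conditional modes; whorl effects remain
    conditionally linearized and the variance parameters stay at their
    ML estimates from the alternating algorithm.
    """
    re_spec = ws.re_spec
    q1, q2 = re_spec.q1, re_spec.q2
    if q1 == 0 or var_spec.correlation != "independent":
        return beta, u1, u2
    if n_nodes is None:
        n_nodes = 5 if q1 <= 2 else 3
    D1s, D2s, delta, cor = _split_theta(theta, re_spec, var_spec)
    D1 = s2 * D1s
    D1inv = np.linalg.inv(D1 + 1e-30 * np.eye(q1))
    ldD1 = np.linalg.slogdet(D1 + 1e-30 * np.eye(q1))[1]
    if q2:
        D2inv = np.linalg.inv(D2s + 1e-14 * np.eye(q2))
        ldD2 = np.linalg.slogdet(D2s + 1e-14 * np.eye(q2))[1]
    # whorl index of each group's first whorl (whorls are contiguous
    # within groups after sorting)
    wg_starts = np.searchsorted(ws.whorl_g1, np.arange(ws.G), side="left")

    zs, wts = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([zs] * q1), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=1)            # (K, q1)
    wgrids = np.meshgrid(*([wts] * q1), indexing="ij")
    logW = np.sum([np.log(w.ravel()) for w in wgrids], axis=0)  # (K,)
    zsq = np.sum(Z * Z, axis=1)
    K = Z.shape[0]
    n_g = np.bincount(ws.obs_g1, minlength=ws.G).astype(float)

    names = ws.names
    beta_cur = dict(beta)
    for _ in range(recenter):
        # adaptive centering from the current conditional modes/information
        mu, Xg, Z1g, Z2g = ws.curve(beta_cur, u1, u2 if q2 else None)
        g = _variance_weights(var_spec, mu, delta)
        marg = _MarginalDiag(ws, Z1g, Z2g, D1s, D2s, g)
        e = ws.y - mu + np.einsum("nq,nq->n", Z1g, u1[ws.obs_g1])
        if q2:
            e = e + np.einsum("nq,nq->n", Z2g, u2[ws.obs_g2])
        u1, u2 = marg.blup(e)
        S = s2 * np.linalg.inv(marg.Mi)
        Lc = np.linalg.cholesky(S)
        ldL = np.log(np.diagonal(Lc, axis1=1, axis2=2)).sum(axis=1)
        u1_nodes = u1[None] + np.sqrt(2.0) * np.einsum("gqr,kr->kgq", Lc, Z)
        logprior = (-0.5 * np.einsum("kgq,qr,kgr->kg", u1_nodes, D1inv, u1_nodes)
                    - 0.5 * (ldD1 + q1 * np.log(2 * np.pi)))
        u2_warm = np.broadcast_to(u2[None], (K, ws.W, q2)).copy() if q2 else None

        def objective(bv):
            bd = dict(zip(names, bv))
            u2k = u2_warm
            scalar2 = q2 == 1  # whorl blocks reduce to scalar arithmetic
            for _it in range(2):
                mu_k, Z2_k = _curve_nodes(ws, bd, u1_nodes, u2k)
                gk = _variance_weights(var_spec, mu_k, delta)
                c = gk * gk
                e_k = ws.y[None] - mu_k
                if q2:
                    e_k = e_k + np.einsum("knq,knq->kn", Z2_k,
                                          u2k[:, ws.obs_g2])
                    Uc = Z2_k / c[..., None]
                    if scalar2:
                        B = np.add.reduceat(Z2_k[..., 0] * Uc[..., 0],
                                            ws.whorl_starts, axis=1) \
                            + D2inv[0, 0]
                        s = np.add.reduceat(Uc[..., 0] * e_k,
                                            ws.whorl_starts, axis=1)
                        u2k = (s / B)[..., None]
                    else:
                        B = np.add.reduceat(
                            np.einsum("knq,knr->knqr", Z2_k, Uc),
                            ws.whorl_starts, axis=1) + D2inv
                        s = np.add.reduceat(Uc * e_k[..., None],
                                            ws.whorl_starts, axis=1)
                        u2k = np.linalg.solve(B, s[..., None])[..., 0]
                else:
                    break
            # conditional marginal (linearized at the whorl modes)
            t = e_k / c
            quad_obs = e_k * t
            if q2:
                if scalar2:
                    Bs = np.add.reduceat(Z2_k[..., 0] * t, ws.whorl_starts,
                                         axis=1) / B
                    lam_e = t - Uc[..., 0] * Bs[:, ws.obs_g2]
                else:
                    Bs = np.linalg.solve(B, np.add.reduceat(
                        Z2_k * t[..., None], ws.whorl_starts, axis=1)[..., None]
                    )[..., 0]
                    lam_e = t - np.einsum("knq,knq->kn", Uc, Bs[:, ws.obs_g2])
                quad_obs = e_k * lam_e
            quad_g = np.add.reduceat(quad_obs, ws.group_starts, axis=1)
            if var_spec.within_group == "constant":
                logdet_w = np.zeros((K, ws.W))
            else:
                logdet_w = np.add.reduceat(np.log(c), ws.whorl_starts, axis=1)
            if q2:
                if scalar2:
                    if np.any(B <= 0):
                        return 1e12
                    ldB = np.log(B)
                else:
                    sgn, ldB = np.linalg.slogdet(B)
                    if np.any(sgn <= 0):
                        return 1e12
                logdet_w = logdet_w + ldB + ldD2
            logdet_g = np.add.reduceat(logdet_w, wg_starts, axis=1)
            llc = -0.5 * (n_g[None] * np.log(2 * np.pi * s2)
                          + logdet_g + quad_g / s2)
            lse = logW[:, None] + zsq[:, None] + llc + logprior
            m = lse.max(axis=0)
            tot = m + np.log(np.sum(np.exp(lse - m[None]), axis=0))
            val = float(np.sum(tot + 0.5 * q1 * np.log(2.0) + ldL))
            return -val if np.isfinite(val) else 1e12

        # optimize in Wald-SE-scaled coordinates: the objective is then
        # close to an isotropic quadratic and BFGS needs few iterations
        try:
            cov = s2 * np.linalg.inv(marg.inner(Xg))
            scales = np.sqrt(np.clip(np.diag(cov), 1e-20, None))
        except np.linalg.LinAlgError:
            scales = np.maximum(np.abs([beta_cur[p] for p in names]), 1e-6) * 0.05
        x0 = np.array([beta_cur[p] for p in names])
        sol = optimize.minimize(lambda z: objective(x0 + scales * z),
                                np.zeros(len(names)), method="BFGS",
                                options={"maxiter": maxiter, "gtol": 2e-2})
        if not np.all(np.isfinite(sol.x)):
            return beta, u1, u2
        beta_cur = dict(zip(names, x0 + scales * sol.x))
    return beta_cur, u1, u2


def _make_marginal(ws, var_spec, Z1, Z2, D1s, D2s, g, cor):
    if var_spec.correlation == "independent":
        return _MarginalDiag(ws, Z1, Z2, D1s, D2s, g)
    Gam = _correlation_matrix(var_spec, ws.lags, cor)
    return _MarginalDense(ws, Z1, Z2, D1s, D2s, g, Gam)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class TwoLevelNLME(BaseEstimator, RegressorMixin):
    """Two-level nonlinear mixed-effects regressor (ML, Lindstrom-Bates).

    Parameters
    ----------
    spec : ModelSpec
        Mean function and covariate expansions.
    level1, level2 : sequence of str
        Parameters perturbed at the primary-branch and whorl level.
    var_spec : VarianceSpec, optional
        Residual variance/correlation structure (identity by default).
    response : str
        Response column when ``y`` is not passed to :meth:`fit`.
    init : dict, optional
        Starting fixed effects (from an NLS fit when omitted).
    max_outer : int
        Maximum alternating iterations.
    tol : float
        Relative log-likelihood change declaring convergence.

    Attributes (after ``fit``)
    --------------------------
    beta_, D1_, D2_, sigma2_, loglik_, aic_, eblups_, converged_,
    result_ (:class:`NLMEResult`).
    """

    def __init__(self, spec: ModelSpec | None = None,
                 level1: Sequence[str] = ("b", "c"),
                 level2: Sequence[str] = ("b",),
                 var_spec: VarianceSpec | None = None,
                 response: str = "SBL", init: dict | None = None,
                 max_outer: int = 200, tol: float = 1e-8,
                 inner_iter: int = 3, theta_maxiter: int = 400,
                 refine: bool = True):
        self.spec = spec
        self.level1 = level1
        self.level2 = level2
        self.var_spec = var_spec
        self.response = response
        self.init = init
        self.max_outer = max_outer
        self.tol = tol
        self.inner_iter = inner_iter
        self.theta_maxiter = theta_maxiter
        self.refine = refine

    # -- internal -----------------------------------------------------------

    def _profiled(self, ws, marg, w, X):
        """Profiled ML of the working LMM: returns (ll, beta, sigma2)."""
        R = np.column_stack([w, X])
        K = marg.inner(R)
        Kxx, Kxw, Kww = K[1:, 1:], K[1:, 0], K[0, 0]
        beta = np.linalg.solve(Kxx + 1e-12 * np.eye(len(Kxw)), Kxw)
        rss = max(Kww - Kxw @ beta, 1e-300)
        n = ws.n
        s2 = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1) - 0.5 * marg.logdet
        return ll, beta, s2, Kxx

    def fit(self, X, y=None):
        spec = self.spec if self.spec is not None else ModelSpec("M7")
        re_spec = RandomEffectsSpec(tuple(self.level1), tuple(self.level2))
        var_spec = self.var_spec if self.var_spec is not None else VarianceSpec()
        data = X.copy()
        if y is not None:
            data = data.assign(**{self.response: np.asarray(y, dtype=float)})
        ws = _Workspace(data, spec, re_spec, self.response)

        # fixed-effects start from the population-average NLS fit
        if self.init is not None:
            beta = {p: float(self.init[p]) for p in ws.names}
            nls_res = None
        else:
            nls_res = _nls.fit(spec, ws.df, response=self.response)
            if not nls_res.converged:
                return self._finish_flagged(ws, re_spec, var_spec,
                                            "NLS initialization failed")
            beta = dict(nls_res.estimates)
        mu0, X0, Z10, Z20 = ws.curve(beta, None, None)
        resid0 = ws.y - mu0
        s2 = float(resid0 @ resid0) / ws.n

        # relative-scale theta start: each effect explains ~5% of residual
        # variance through its gradient column
        th = []
        for q, Z in ((re_spec.q1, Z10), (re_spec.q2, Z20)):
            for i in range(q):
                for j in range(i + 1):
                    if i == j:
                        msq = float(np.mean(Z[:, i] ** 2)) or 1.0
                        th.append(0.5 * np.log(0.05 / msq))
                    else:
                        th.append(0.0)
        th += [0.0] * (var_spec.n_var_params + var_spec.n_cor_params)
        theta = np.array(th)

        u1 = np.zeros((ws.G, re_spec.q1))
        u2 = np.zeros((ws.W, re_spec.q2))
        ll_prev, ll = -np.inf, -np.inf
        beta_v = np.array([beta[p] for p in ws.names])
        converged = False
        message = "max outer iterations reached"
        n_outer = 0
        Kxx = None
        theta0 = theta.copy()
        beta0 = beta_v.copy()
        restarted = False
        # admissible box of the mean function (covariate slopes are free)
        blo = np.array([spec.function.bounds.get(p, (-np.inf, np.inf))[0]
                        for p in ws.names])
        bhi = np.array([spec.function.bounds.get(p, (-np.inf, np.inf))[1]
                        for p in ws.names])

        def build_marginal(th_vec, mu, Z1, Z2):
            D1s, D2s, delta, cor = _split_theta(th_vec, re_spec, var_spec)
            g = _variance_weights(var_spec, mu, delta)
            return _make_marginal(ws, var_spec, Z1, Z2, D1s, D2s, g, cor)

        try:
            for n_outer in range(1, self.max_outer + 1):
                # ---- conditional-mode (penalized GN) sweeps ----
                for _ in range(self.inner_iter):
                    mu, Xg, Z1, Z2 = ws.curve(beta, u1, u2)
                    marg = build_marginal(theta, mu, Z1, Z2)
                    e = ws.y - mu
                    if re_spec.q1:
                        e = e + np.einsum("nq,nq->n", Z1, u1[ws.obs_g1])
                    if re_spec.q2:
                        e = e + np.einsum("nq,nq->n", Z2, u2[ws.obs_g2])
                    u1, u2 = marg.blup(e)
                    if not (np.all(np.isfinite(u1)) and np.all(np.isfinite(u2))):
                        u1 = np.zeros((ws.G, re_spec.q1))
                        u2 = np.zeros((ws.W, re_spec.q2))
                    else:
                        # modes beyond 8 prior SDs signal a diverging
                        # linearization, never a real posterior
                        D1s_c, D2s_c, _, _ = _split_theta(theta, re_spec,
                                                          var_spec)
                        if re_spec.q1:
                            cap = 8 * np.sqrt(np.diag(D1s_c) * s2) + 1e-12
                            u1 = np.clip(u1, -cap, cap)
                        if re_spec.q2:
                            cap = 8 * np.sqrt(np.diag(D2s_c) * s2) + 1e-12
                            u2 = np.clip(u2, -cap, cap)

                # ---- working linearization at the modes ----
                mu, Xg, Z1, Z2 = ws.curve(beta, u1, u2)
                w = ws.y - mu + Xg @ beta_v
                if re_spec.q1:
                    w = w + np.einsum("nq,nq->n", Z1, u1[ws.obs_g1])
                if re_spec.q2:
                    w = w + np.einsum("nq,nq->n", Z2, u2[ws.obs_g2])

                # ---- profiled ML over theta ----
                msq1 = np.mean(Z1**2, axis=0) if re_spec.q1 else None
                msq2 = np.mean(Z2**2, axis=0) if re_spec.q2 else None

                def nll(th_vec):
                    D1s_t, D2s_t, delta_t, _ = _split_theta(th_vec, re_spec,
                                                            var_spec)
                    # reject variance ratios far beyond what the data can
                    # carry (a single effect claiming >50x the weighted
                    # residual variance through its gradient column)
                    g2 = float(np.mean(
                        _variance_weights(var_spec, mu, delta_t) ** 2))
                    if re_spec.q1 and np.any(np.diag(D1s_t) * msq1 > 50 * g2):
                        return 1e12
                    if re_spec.q2 and np.any(np.diag(D2s_t) * msq2 > 50 * g2):
                        return 1e12
                    try:
                        m = build_marginal(th_vec, mu, Z1, Z2)
                    except np.linalg.LinAlgError:
                        return 1e12
                    val = self._profiled(ws, m, w, Xg)[0]
                    return -val if np.isfinite(val) else 1e12

                if len(theta):
                    maxit = self.theta_maxiter if n_outer == 1 else 80
                    starts = [theta]
                    if n_outer == 1 and (var_spec.n_var_params
                                         or var_spec.n_cor_params):
                        # the variance-function/correlation directions are
                        # prone to local basins; seed a few alternatives
                        ix = _n_theta(re_spec, VarianceSpec())
                        for dv in (0.5, 1.0):
                            alt = theta.copy()
                            if var_spec.n_var_params:
                                alt[ix] = dv
                            if var_spec.n_cor_params:
                                alt[ix + var_spec.n_var_params] = dv
                            starts.append(alt)
                    best = None
                    for st in starts:
                        sol = optimize.minimize(
                            nll, st, method="Nelder-Mead",
                            options={"maxiter": maxit, "xatol": 1e-6,
                                     "fatol": 1e-9, "adaptive": True})
                        if best is None or sol.fun < best.fun:
                            best = sol
                    theta = best.x
                marg = build_marginal(theta, mu, Z1, Z2)
                beta_prev = beta_v.copy()
                ll, beta_v, s2, Kxx = self._profiled(ws, marg, w, Xg)
                # project back into the admissible region of the curve
                beta_v = np.clip(beta_v, blo + 1e-12, bhi)
                # damped acceptance: the working-model GLS step must not
                # worsen the conditional (nonlinear) residual sum
                if np.all(np.isfinite(beta_v)):
                    r_old = ws.y - ws.mean(dict(zip(ws.names, beta_prev)),
                                           u1, u2)
                    rss_old = float(np.nansum(r_old**2))
                    alpha = 1.0
                    for _ in range(6):
                        cand = beta_prev + alpha * (beta_v - beta_prev)
                        cand = np.clip(cand, blo + 1e-12, bhi)
                        r_new = ws.y - ws.mean(dict(zip(ws.names, cand)),
                                               u1, u2)
                        rss_new = float(np.nansum(r_new**2))
                        if np.isfinite(rss_new) and rss_new <= rss_old * 1.001:
                            beta_v = cand
                            break
                        alpha *= 0.5
                    else:
                        beta_v = beta_prev  # no productive step found
                beta = dict(zip(ws.names, beta_v))

                if not (np.isfinite(ll) and np.all(np.isfinite(beta_v))):
                    if restarted:
                        return self._finish_flagged(
                            ws, re_spec, var_spec,
                            "diverged after ridge restart")
                    # ridge restart: back to the NLS start and fresh theta
                    restarted = True
                    theta = theta0.copy()
                    beta_v = beta0.copy()
                    beta = dict(zip(ws.names, beta_v))
                    u1 = np.zeros((ws.G, re_spec.q1))
                    u2 = np.zeros((ws.W, re_spec.q2))
                    ll_prev, ll = -np.inf, -np.inf
                    continue

                if np.isfinite(ll) and abs(ll - ll_prev) < self.tol * (abs(ll) + 1):
                    converged = True
                    message = f"relative logLik change < {self.tol}"
                    break
                ll_prev = ll
        except np.linalg.LinAlgError as exc:
            return self._finish_flagged(ws, re_spec, var_spec,
                                        f"linear algebra failure: {exc}")

        if self.refine and converged:
            try:
                beta, u1, u2 = _agq_refine(ws, var_spec, beta, theta, s2, u1, u2)
            except np.linalg.LinAlgError:
                pass  # keep the LB estimates if refinement centering fails
        return self._finish(ws, re_spec, var_spec, beta, theta, s2, u1, u2,
                            converged, n_outer, message, Kxx)

    def _finish_flagged(self, ws, re_spec, var_spec, message):
        nan = {p: np.nan for p in ws.names}
        self.result_ = NLMEResult(
            spec=ws.spec, re_spec=re_spec, var_spec=var_spec, beta=nan,
            se=dict(nan), pvalues=dict(nan),
            D1=pd.DataFrame(np.full((re_spec.q1, re_spec.q1), np.nan),
                            index=re_spec.level1_params,
                            columns=re_spec.level1_params),
            D2=pd.DataFrame(np.full((re_spec.q2, re_spec.q2), np.nan),
                            index=re_spec.level2_params,
                            columns=re_spec.level2_params),
            sigma2=np.nan, var_params={}, loglik=np.nan, aic=np.nan,
            n=ws.n, n_params=0, eblups_level1=pd.DataFrame(),
            eblups_level2=pd.DataFrame(), mae=np.nan, rmse=np.nan,
            ra2=np.nan, converged=False, iterations=0, message=message)
        self.converged_ = False
        self.beta_ = nan
        return self

    def _finish(self, ws, re_spec, var_spec, beta, theta, s2, u1, u2,
                converged, iterations, message, Kxx):
        D1s, D2s, delta, cor = _split_theta(theta, re_spec, var_spec)
        D1 = s2 * D1s
        D2 = s2 * D2s
        # final mode refinement + Laplace log-likelihood at the estimates
        ll, u1, u2 = _laplace_loglik(ws, var_spec, beta, theta, s2, u1, u2)
        p = len(ws.names)
        k = p + _n_theta(re_spec, var_spec) + 1
        aic = -2 * ll + 2 * k

        # Wald SEs from the working GLS information (sigma2 * (X'V*^-1 X)^-1)
        se, pv = {}, {}
        if Kxx is not None:
            try:
                cov = s2 * np.linalg.inv(Kxx)
                sd = np.sqrt(np.clip(np.diag(cov), 0, None))
                bv = np.array([beta[p_] for p_ in ws.names])
                z = bv / np.where(sd > 0, sd, np.inf)
                se = dict(zip(ws.names, sd))
                pv = dict(zip(ws.names, 2 * stats.norm.sf(np.abs(z))))
            except np.linalg.LinAlgError:
                se = {p_: np.nan for p_ in ws.names}
                pv = dict(se)

        # conditional (subject-specific) fit indices
        mu, *_ = ws.curve(beta, u1, u2)
        r = ws.y - mu
        rss = float(r @ r)
        sst = float(np.sum((ws.y - ws.y.mean()) ** 2))
        r2 = 1 - rss / sst if sst > 0 else np.nan
        ra2 = 1 - (1 - r2) * (ws.n - 1) / (ws.n - p - 1)

        eb1 = pd.DataFrame(u1, columns=list(re_spec.level1_params))
        eb1.insert(0, "branch_id", [k[1] for k in ws.g1_keys])
        eb1.insert(0, "tree_id", [k[0] for k in ws.g1_keys])
        eb2 = pd.DataFrame(u2, columns=list(re_spec.level2_params))
        eb2.insert(0, "whorl_id", [k[2] for k in ws.g2_keys])
        eb2.insert(0, "branch_id", [k[1] for k in ws.g2_keys])
        eb2.insert(0, "tree_id", [k[0] for k in ws.g2_keys])

        var_params = {}
        if var_spec.n_var_params:
            var_params["delta"] = float(delta)
        for i, c in enumerate(np.atleast_1d(cor)):
            var_params[f"cor{i + 1}"] = float(c)

        self.result_ = NLMEResult(
            spec=ws.spec, re_spec=re_spec, var_spec=var_spec,
            beta={p_: float(beta[p_]) for p_ in ws.names}, se=se, pvalues=pv,
            D1=pd.DataFrame(D1, index=re_spec.level1_params,
                            columns=re_spec.level1_params),
            D2=pd.DataFrame(D2, index=re_spec.level2_params,
                            columns=re_spec.level2_params),
            sigma2=float(s2), var_params=var_params, loglik=float(ll),
            aic=float(aic), n=ws.n, n_params=k,
            eblups_level1=eb1, eblups_level2=eb2,
            mae=float(np.mean(np.abs(r))), rmse=float(np.sqrt(rss / ws.n)),
            ra2=float(ra2), converged=converged, iterations=iterations,
            message=message)
        self.beta_ = self.result_.beta
        self.D1_ = self.result_.D1
        self.D2_ = self.result_.D2
        self.sigma2_ = float(s2)
        self.loglik_ = float(ll)
        self.aic_ = float(aic)
        self.eblups_ = (eb1, eb2)
        self.converged_ = converged
        self._ws_keys = (ws.g1_keys, ws.g2_keys)
        return self

    def predict(self, X, mode: str = "population"):
        """Predicted sizes; ``subject`` adds EBLUPs for known groups and
        falls back to population values for unseen ones."""
        res = self.result_
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        params = {p: np.full(len(df), res.beta[p]) for p in res.beta}
        if mode == "subject":
            eb1, eb2 = res.eblups_level1, res.eblups_level2
            m1 = df.merge(eb1, on=["tree_id", "branch_id"], how="left") \
                if {"tree_id", "branch_id"} <= set(df.columns) else None
            m2 = df.merge(eb2, on=["tree_id", "branch_id", "whorl_id"],
                          how="left") \
                if {"tree_id", "branch_id", "whorl_id"} <= set(df.columns) else None
            for p in res.re_spec.level1_params:
                if m1 is not None:
                    params[p] = params[p] + m1[p].fillna(0.0).to_numpy()
            for p in res.re_spec.level2_params:
                if m2 is not None:
                    params[p] = params[p] + m2[p].fillna(0.0).to_numpy()
        elif mode != "population":
            raise ValueError("mode must be 'population' or 'subject'")
        return evaluate(res.spec, params, df["SDINC"], df, check=False)


def _laplace_loglik(ws, var_spec, beta, theta, s2, u1, u2,
                    max_iter=50, tol=1e-10):
    """Laplace-approximate marginal logLik at fixed parameters.

    Refines the conditional modes by penalized GN and evaluates the
    marginal Gaussian likelihood of the model linearized at the modes —
    exact whenever f is linear in the random effects.
    """
    re_spec = ws.re_spec
    for _ in range(max_iter):
        mu, Xg, Z1, Z2 = ws.curve(beta, u1, u2)
        D1s, D2s, delta, cor = _split_theta(theta, re_spec, var_spec)
        g = _variance_weights(var_spec, mu, delta)
        marg = _make_marginal(ws, var_spec, Z1, Z2, D1s, D2s, g, cor)
        e = ws.y - mu
        if re_spec.q1:
            e = e + np.einsum("nq,nq->n", Z1, u1[ws.obs_g1])
        if re_spec.q2:
            e = e + np.einsum("nq,nq->n", Z2, u2[ws.obs_g2])
        n1, n2 = marg.blup(e)
        step = max(
            float(np.max(np.abs(n1 - u1))) if re_spec.q1 else 0.0,
            float(np.max(np.abs(n2 - u2))) if re_spec.q2 else 0.0)
        u1, u2 = n1, n2
        if step < tol:
            break
    mu, Xg, Z1, Z2 = ws.curve(beta, u1, u2)
    e = ws.y - mu
    if re_spec.q1:
        e = e + np.einsum("nq,nq->n", Z1, u1[ws.obs_g1])
    if re_spec.q2:
        e = e + np.einsum("nq,nq->n", Z2, u2[ws.obs_g2])
    D1s, D2s, delta, cor = _split_theta(theta, re_spec, var_spec)
    g = _variance_weights(var_spec, mu, delta)
    marg = _make_marginal(ws, var_spec, Z1, Z2, D1s, D2s, g, cor)
    quad = float(marg.inner(e[:, None])[0, 0])
    ll = -0.5 * (ws.n * np.log(2 * np.pi * s2) + marg.logdet + quad / s2)
    return float(ll), u1, u2


# --------------------------------------------------------------------------
# module-level operations
# --------------------------------------------------------------------------

def fit_nlme(spec: ModelSpec, re_spec: RandomEffectsSpec,
             var_spec: VarianceSpec | None, data: pd.DataFrame,
             init: dict | None = None, response: str = "SBL",
             **kw) -> NLMEResult:
    """Fit the two-level model by ML; flagged result on failure."""
    est = TwoLevelNLME(spec=spec, level1=re_spec.level1_params,
                       level2=re_spec.level2_params, var_spec=var_spec,
                       response=response, init=init, **kw)
    est.fit(data)
    return est.result_


def loglik(result: NLMEResult, data: pd.DataFrame,
           response: str | None = None) -> float:
    """Standalone Laplace log-likelihood of ``data`` at a fit's parameters."""
    resp = response or ("SBD" if "b1" in result.beta else "SBL")
    ws = _Workspace(data, result.spec, result.re_spec, resp)
    s2 = result.sigma2
    theta = np.concatenate([
        _chol_pack(result.D1.to_numpy() / s2) if result.re_spec.q1 else [],
        _chol_pack(result.D2.to_numpy() / s2) if result.re_spec.q2 else [],
        [result.var_params.get("delta", 0.0)] * result.var_spec.n_var_params,
        [result.var_params.get(f"cor{i+1}", 0.0)
         for i in range(result.var_spec.n_cor_params)],
    ])
    u1 = np.zeros((ws.G, result.re_spec.q1))
    u2 = np.zeros((ws.W, result.re_spec.q2))
    ll, *_ = _laplace_loglik(ws, result.var_spec, result.beta, theta, s2, u1, u2)
    return ll


def lrt(nested: NLMEResult | _nls.FitResult,
        full: NLMEResult | _nls.FitResult):
    """Likelihood-ratio test of a nested against a full fit.

    Returns (statistic, df, p). When the restriction puts a variance on
    the boundary the chi-square reference is conservative; the p-value
    is still reported against chi2(df).
    """
    k_nested = nested.n_params if isinstance(nested, NLMEResult) \
        else nested.n_params + 1
    k_full = full.n_params if isinstance(full, NLMEResult) \
        else full.n_params + 1
    if k_full < k_nested:
        raise ValueError("full model has fewer parameters than nested model")
    stat = 2.0 * (full.loglik - nested.loglik)
    stat = max(stat, 0.0)
    df = k_full - k_nested
    p = float(stats.chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return float(stat), int(df), p


def search_random_effects(spec: ModelSpec, data: pd.DataFrame,
                          max_random: int = 3,
                          candidates: Sequence[str] | None = None,
                          combos: Sequence[tuple] | None = None,
                          response: str = "SBL", **kw) -> pd.DataFrame:
    """Enumerate level-1 x level-2 random-effect placements, rank by AIC.

    ``candidates`` restricts which parameters may carry effects
    (default: all free parameters); ``combos`` supplies an explicit list
    of ``(level1_tuple, level2_tuple)`` pairs instead of the full
    enumeration. ``max_random = 0`` reduces to the fixed-effects fit.
    """
    names = candidates if candidates is not None else free_params(spec)
    nls_res = _nls.fit(spec, data, response=response)
    rows = []
    if combos is None:
        combos = []
        for r1 in range(0, max_random + 1):
            for l1 in itertools.combinations(names, r1):
                for r2 in range(0, max_random + 1 - r1):
                    for l2 in itertools.combinations(names, r2):
                        combos.append((l1, l2))
    for l1, l2 in combos:
        if not l1 and not l2:
            rows.append({"level1": (), "level2": (), "aic": nls_res.aic,
                         "loglik": nls_res.loglik,
                         "converged": nls_res.converged, "result": nls_res})
            continue
        res = fit_nlme(spec, RandomEffectsSpec(l1, l2), None, data,
                       init=dict(nls_res.estimates)
                       if nls_res.converged else None,
                       response=response, **kw)
        rows.append({"level1": tuple(l1), "level2": tuple(l2),
                     "aic": res.aic, "loglik": res.loglik,
                     "converged": res.converged, "result": res})
    if not rows:
        rows.append({"level1": (), "level2": (), "aic": nls_res.aic,
                     "loglik": nls_res.loglik,
                     "converged": nls_res.converged, "result": nls_res})
    table = pd.DataFrame(rows)
    return table.sort_values(["converged", "aic"], ascending=[False, True],
                             na_position="last").reset_index(drop=True)


def predict(result: NLMEResult, new_rows: pd.DataFrame,
            mode: str = "population") -> np.ndarray:
    """Predict sizes from a fitted result (see :meth:`TwoLevelNLME.predict`)."""
    est = TwoLevelNLME(spec=result.spec)
    est.result_ = result
    return est.predict(new_rows, mode=mode)
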