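"""Allometric scaling between primary- and secondary-branch sizes.

Paired sizes follow a power law ``y = a * x^b``; taking logs gives the
linear form ``log y = gamma + b*log x`` with ``gamma = log a``, fitted by
ordinary least squares. The slope ``b`` is the scaling exponent;
confidence intervals come from the percentile bootstrap over case
resampling (3,000 replicates and a 95% level by default).

Three grouping levels are analyzed, pairing each secondary branch (or
the basal one) with its parent primary branch:

* by primary-branch age — primary size vs the size of the secondary
  branch attached at the primary-branch base (deepest whorl);
* by secondary-branch age — secondary size vs the distance from the
  primary-branch tip to its attachment point (length), or the parent
  branch diameter scaled to that point (diameter; an approximation, as
  mid-branch diameters are not measured);
* by tree age — basal pairing again, grouped by stand age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from pinecrown.synth import BranchDataset

__all__ = [
    "AllometryFit",
    "PowerLawAllometry",
    "fit_loglog",
    "bootstrap_ci",
    "scaling_profile",
]

MIN_PAIRS = 5


@dataclass
class AllometryFit:
    """Log-log OLS fit of one group plus its bootstrap percentile CI."""

    group: str
    n: int
    gamma: float
    exponent: float
    gamma_ci: tuple[float, float]
    exponent_ci: tuple[float, float]
    B: int
    level: float
    reliable: bool = True


def _validate_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    bad = np.flatnonzero((x <= 0) | (y <= 0))
    if len(bad):
        raise ValueError(f"nonpositive values at rows {bad.tolist()[:10]}")
    return x, y


def fit_loglog(x, y) -> tuple[float, float]:
    """OLS of log(y) on log(x): returns (gamma, exponent)."""
    x, y = _validate_pairs(x, y)
    lx, ly = np.log(x), np.log(y)
    sb = np.cov(lx, ly, ddof=1)[0, 1] / np.var(lx, ddof=1)
    return float(ly.mean() - sb * lx.mean()), float(sb)


def bootstrap_ci(x, y, B: int = 3000, level: float = 0.95,
                 seed: int | np.random.Generator = 0):
    """Percentile-bootstrap CIs for (gamma, exponent) by case resampling.

    Deterministic given ``seed``; returns ``(gamma_ci, exponent_ci)``
    where each is the pair of empirical (1 +/- level)/2 quantiles of the
    replicate estimates.
    """
    x, y = _validate_pairs(x, y)
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(x)
    lx, ly = np.log(x), np.log(y)
    idx = rng.integers(0, n, size=(B, n))
    sx, sy = lx[idx], ly[idx]
    mx = sx.mean(axis=1)
    my = sy.mean(axis=1)
    vx = ((sx - mx[:, None]) ** 2).sum(axis=1)
    cxy = ((sx - mx[:, None]) * (sy - my[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = cxy / vx
    gammas = my - slopes * mx
    alpha = (1.0 - level) / 2.0
    qs = [alpha, 1.0 - alpha]
    g_lo, g_hi = np.nanquantile(gammas, qs)
    e_lo, e_hi = np.nanquantile(slopes, qs)
    return (float(g_lo), float(g_hi)), (float(e_lo), float(e_hi))


class PowerLawAllometry(BaseEstimator):
    """Log-log power-law regression with percentile-bootstrap intervals.

    Parameters
    ----------
    B : int
        Bootstrap replicates (3,000 by default).
    level : float
        Confidence level (0.95 by default).
    seed : int
        Seed for the case-resampling generator.

    Attributes (after ``fit``)
    --------------------------
    gamma_, exponent_ : point estimates on the log scale
    amplitude_ : exp(gamma_), the power-law normalization constant
    gamma_ci_, exponent_ci_ : percentile intervals
    """

    def __init__(self, B: int = 3000, level: float = 0.95, seed: int = 0):
        self.B = B
        self.level = level
        self.seed = seed

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        self.gamma_, self.exponent_ = fit_loglog(x, y)
        self.amplitude_ = float(np.exp(self.gamma_))
        self.gamma_ci_, self.exponent_ci_ = bootstrap_ci(
            x, y, B=self.B, level=self.level, seed=self.seed)
        self.n_ = len(y)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.amplitude_ * x ** self.exponent_


def _basal_pairs(dataset: BranchDataset) -> pd.DataFrame:
    """Primary branches paired with the secondary branch at their base
    (deepest whorl, i.e. maximum SDINC)."""
    sec = dataset.secondaries
    deepest = sec.loc[sec.groupby(["tree_id", "branch_id"])["SDINC"].idxmax()]
    pairs = deepest.merge(dataset.primaries, on=["tree_id", "branch_id"])
    return pairs.merge(dataset.trees[["tree_id", "age"]], on="tree_id")


def scaling_profile(dataset: BranchDataset, grouping: str = "primary_age",
                    measure: str = "length", B: int = 3000,
                    level: float = 0.95, seed: int = 0) -> list[AllometryFit]:
    """Per-group log-log fits with bootstrap CIs at one grouping level.

    ``grouping``: 'primary_age' (PAGE), 'secondary_age' (SAGE) or
    'tree_age'; ``measure``: 'length' or 'diameter'. Groups with fewer
    than 5 pairs are fitted but flagged unreliable (or skipped when a
    log-log fit is impossible).
    """
    if measure not in ("length", "diameter"):
        raise ValueError("measure must be 'length' or 'diameter'")
    rng = np.random.default_rng(seed)
    if grouping in ("primary_age", "tree_age"):
        pairs = _basal_pairs(dataset)
        key = "PAGE" if grouping == "primary_age" else "age"
        xcol, ycol = ("SBL", "PBL") if measure == "length" else ("SBD", "PBD")
    elif grouping == "secondary_age":
        pairs = dataset.secondaries.merge(
            dataset.primaries, on=["tree_id", "branch_id"])
        key = "SAGE"
        if measure == "length":
            xcol, ycol = "SBL", "SDINC"
        else:
            # parent diameter scaled to the attachment point stands in for
            # the unmeasured mid-branch diameter
            pairs = pairs.assign(PBD_at=pairs["PBD"]
                                 * pairs["SDINC"] / pairs["PBL"])
            xcol, ycol = "SBD", "PBD_at"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if pairs.empty:
        raise ValueError("no resolvable pairs in dataset")

    fits: list[AllometryFit] = []
    for gval, sub in pairs.groupby(key, sort=True):
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        keep = (x > 0) & (y > 0)
        x, y = x[keep], y[keep]
        if len(x) < 3:
            continue
        gamma, expo = fit_loglog(x, y)
        g_ci, e_ci = bootstrap_ci(x, y, B=B, level=level, seed=rng)
        fits.append(AllometryFit(
            group=f"{key}={gval}", n=len(x), gamma=gamma, exponent=expo,
            gamma_ci=g_ci, exponent_ci=e_ci, B=B, level=level,
            reliable=len(x) >= MIN_PAIRS))
    if not fits:
        raise ValueError("no group reached the minimum pair count")
    return fits
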