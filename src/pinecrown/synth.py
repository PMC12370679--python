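"""Synthetic hierarchical crown data for planted Korean pine.

Emulates the hierarchical structure of a felled-tree branch census:
sample trees (six even-aged stands, ages 28-70 years), primary branches
along each crown, annual whorls of secondary branches nested in each
primary branch, and one row per measured secondary branch. Covariates
are drawn from truncated normal distributions matched to the published
summary envelopes (min / mean / max / sd) of the study's sample; the
two size responses follow the unimodal Roeecp law

    SBL_ijk = (a + a1*PDINC_i) * SDINC_ijk^(b + b_i + b_ij)
              * exp(-(c + c_i)*SDINC_ijk) + e_ijk
    SBD_ijk = a * SDINC_ijk^(b + b_i + (b1 + b_ij1)*PBD_i)
              * exp(-(c + c_i)*SDINC_ijk) + e_ijk

with primary-branch effects (b_i, c_i) ~ N(0, D1), whorl effects
b_ij (resp. b_ij1) ~ N(0, sigma2_bij) and residuals e ~ N(0, sigma2).

The reported variance-parameter tables print the (b_i, c_i) cross term
(0.842 for length, 0.891 for diameter) at a magnitude that exceeds
sqrt(var_b * var_c); it is therefore interpreted here as the
*correlation* between b_i and c_i, not their covariance — a covariance
that large would make D1 indefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Envelope",
    "GeneratorConfig",
    "BranchDataset",
    "DEFAULT_ENVELOPES",
    "RESPONSE_LAWS",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: flat-file schema, one row per secondary branch
SCHEMA = [
    "tree_id", "branch_id", "whorl_id", "obs_id",
    "age", "DBH", "HT", "CW", "HBLC", "CL", "CR", "HD",
    "PAGE", "PBL", "PBD", "PBC", "PAZ", "PVA", "PDINC",
    "SAGE", "SDINC", "SBL", "SBD",
]

TREE_COLS = ["tree_id", "age", "DBH", "HT", "CW", "HBLC", "CL", "CR", "HD"]
PRIMARY_COLS = ["tree_id", "branch_id", "PAGE", "PBL", "PBD", "PBC", "PAZ", "PVA", "PDINC"]
SECONDARY_COLS = ["tree_id", "branch_id", "whorl_id", "obs_id", "SAGE", "SDINC", "SBL", "SBD"]

STAND_AGES = (28, 40, 46, 53, 64, 70)


@dataclass(frozen=True)
class Envelope:
    """Published summary envelope of one covariate: min <= mean <= max, sd >= 0."""

    min: float
    mean: float
    max: float
    sd: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"envelope requires min <= mean <= max, got {self}")
        if self.sd < 0:
            raise ValueError("envelope sd must be >= 0")


# Published sample summaries: 54 trees, 717 primary branches, 24,053
# secondary branches.
DEFAULT_ENVELOPES: dict[str, Envelope] = {
    "DBH": Envelope(7.30, 28.23, 44.60, 8.34),     # cm
    "HT": Envelope(6.72, 17.70, 24.92, 4.35),      # m
    "CW": Envelope(1.27, 2.45, 3.98, 0.62),        # m
    "HBLC": Envelope(1.34, 8.77, 15.69, 4.07),     # m
    "HD": Envelope(0.41, 0.65, 1.09, 0.12),
    "PAGE": Envelope(2, 11, 34, 6.52),             # years
    "PBL": Envelope(8.00, 244.14, 661.00, 144.77),  # cm
    "PBD": Envelope(4.32, 29.81, 75.01, 14.49),    # mm
    "PBC": Envelope(7.00, 217.27, 640.00, 127.23),  # cm
    "PAZ": Envelope(0, 179, 355, 104.98),          # degrees
    "PVA": Envelope(0, 60, 110, 13.50),            # degrees
    "SAGE": Envelope(1, 7, 32, 4.38),              # years
    "SBL": Envelope(0.50, 25.91, 218.00, 23.38),   # cm
    "SBD": Envelope(0.40, 5.71, 37.76, 2.59),      # mm
}


def _law(fixed, var_b, var_c, corr, level2_var, sigma2):
    cov = corr * np.sqrt(var_b * var_c)
    return {
        "fixed_effects": fixed,
        "level1_cov": np.array([[var_b, cov], [cov, var_c]]),
        "level2_var": level2_var,
        "sigma2": sigma2,
    }


#: generating laws at the published parameter estimates. ``*_mixed`` carry
#: the two-level random-effect structure; ``*_fixed`` are the
#: population-average covariate-extended models (residual sd set to the
#: published fit RMSE).
RESPONSE_LAWS: dict[str, dict] = {
    "SBL_mixed": _law(
        {"a": 0.197, "a1": 3.0e-4, "b": 0.989, "c": 0.003},
        6.2e-3, 4.0e-6, 0.842, 1.9e-3, 251.6,
    ),
    "SBD_mixed": _law(
        {"a": 1.321, "b": 0.270, "b1": 2.2e-3, "c": 1.4e-3},
        2.1e-3, 1.9e-6, 0.891, 4.1e-7, 3.649,
    ),
    "SBL_fixed": {
        "fixed_effects": {"a": 0.188, "a1": 3.0e-4, "b": 0.974, "c": 0.002},
        "level1_cov": np.zeros((2, 2)),
        "level2_var": 0.0,
        "sigma2": 18.96**2,
    },
    "SBD_fixed": {
        "fixed_effects": {"a": 1.292, "b": 0.276, "b1": 1.9e-3, "c": 1.2e-3},
        "level1_cov": np.zeros((2, 2)),
        "level2_var": 0.0,
        "sigma2": 2.236**2,
    },
}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; deterministic given ``seed``.

    ``branches_per_tree`` and ``whorls_per_branch`` accept a fixed int or
    an inclusive ``(low, high)`` range; ``whorls_per_branch="annual"``
    gives one whorl per secondary-branch age class up to the branch age.
    ``obs_per_whorl`` accepts an int or ``"default"`` (1 + Poisson(2)).
    """

    n_trees: int = 54
    branches_per_tree: int | tuple[int, int] = (11, 16)
    whorls_per_branch: int | tuple[int, int] | str = "annual"
    obs_per_whorl: int | str = "default"
    response_law: str = "SBL_mixed"
    fixed_effects: Mapping[str, float] | None = None
    level1_cov: np.ndarray | None = None
    level2_var: float | None = None
    sigma2: float | None = None
    covariate_envelopes: Mapping[str, Envelope] = field(
        default_factory=lambda: dict(DEFAULT_ENVELOPES)
    )
    #: "keep" retains the exact Gaussian error law (occasional nonpositive
    #: sizes possible); "redraw" rejects and redraws nonpositive rows.
    nonpositive: str = "keep"
    seed: int = 0

    def __post_init__(self):
        if self.response_law not in RESPONSE_LAWS:
            raise ValueError(f"unknown response_law {self.response_law!r}")
        law = RESPONSE_LAWS[self.response_law]
        if self.fixed_effects is None:
            self.fixed_effects = dict(law["fixed_effects"])
        if self.level1_cov is None:
            self.level1_cov = np.array(law["level1_cov"], dtype=float)
        else:
            self.level1_cov = np.asarray(self.level1_cov, dtype=float)
        if self.level2_var is None:
            self.level2_var = float(law["level2_var"])
        if self.sigma2 is None:
            self.sigma2 = float(law["sigma2"])
        if self.sigma2 < 0 or self.level2_var < 0:
            raise ValueError("variances must be >= 0")
        D1 = self.level1_cov
        if D1.shape != (2, 2) or not np.allclose(D1, D1.T):
            raise ValueError("level1_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(D1)) < -1e-12:
            raise ValueError("level1_cov must be positive semidefinite")
        if self.nonpositive not in ("keep", "redraw"):
            raise ValueError("nonpositive must be 'keep' or 'redraw'")
        for name, env in self.covariate_envelopes.items():
            if not isinstance(env, Envelope):
                self.covariate_envelopes[name] = Envelope(*env)


@dataclass
class BranchDataset:
    """Hierarchical branch data: trees, primary branches, secondary branches.

    ``effects_level1`` / ``effects_level2`` and the ``mu`` column of
    ``secondaries`` hold the drawn random effects and conditional means
    when the dataset was simulated; they are in-memory diagnostics only
    and are not written to file.
    """

    trees: pd.DataFrame
    primaries: pd.DataFrame
    secondaries: pd.DataFrame
    provenance: GeneratorConfig | str | None = None
    effects_level1: pd.DataFrame | None = None
    effects_level2: pd.DataFrame | None = None
    rejection_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Flat analysis table, one row per secondary branch (schema columns)."""
        df = self.secondaries.merge(self.primaries, on=["tree_id", "branch_id"])
        df = df.merge(self.trees, on="tree_id")
        return df[SCHEMA]

    @property
    def n_secondaries(self) -> int:
        return len(self.secondaries)


def _truncnorm(rng, env: Envelope, size, mean=None, sd=None):
    m = env.mean if mean is None else mean
    s = env.sd if sd is None else sd
    if s <= 0:
        return np.full(size, m)
    a, b = (env.min - m) / s, (env.max - m) / s
    return stats.truncnorm.rvs(a, b, loc=m, scale=s, size=size, random_state=rng)


def _count(rng, spec, n) -> np.ndarray:
    if isinstance(spec, (int, np.integer)):
        return np.full(n, int(spec))
    lo, hi = spec
    return rng.integers(lo, hi + 1, size=n)


def _response_mean(law: str, fx: Mapping[str, float], sdinc, pdinc, pbd,
                   b_i=0.0, c_i=0.0, b_whorl=0.0):
    """Conditional mean given the drawn random effects."""
    if law.startswith("SBL"):
        amp = fx["a"] + fx["a1"] * pdinc
        expo = fx["b"] + b_i + b_whorl
    else:
        amp = fx["a"]
        expo = fx["b"] + b_i + (fx["b1"] + b_whorl) * pbd
    return amp * sdinc**expo * np.exp(-(fx["c"] + c_i) * sdinc)


def generate_dataset(config: GeneratorConfig) -> BranchDataset:
    """Simulate one hierarchical branch census.

    Deterministic given ``config.seed``. Tree and branch covariates are
    truncated normals inside their envelopes; branch diameter follows a
    log-linear relation to branch length plus noise; branch depth in the
    crown (PDINC) increases with branch age so deeper branches are
    older; whorl positions sit at j/(n_whorls+1) of the branch length
    with jitter, one whorl per secondary-branch age class.
    """
    rng = np.random.default_rng(config.seed)
    env = config.covariate_envelopes
    fx = dict(config.fixed_effects)
    law = config.response_law

    n_trees = config.n_trees
    ages = np.array([STAND_AGES[t % len(STAND_AGES)] for t in range(n_trees)])

    # --- tree level -------------------------------------------------------
    DBH = _truncnorm(rng, env["DBH"], n_trees)
    HT = _truncnorm(rng, env["HT"], n_trees)
    CW = _truncnorm(rng, env["CW"], n_trees)
    # crown base sits strictly below the tip: clip the envelope at 0.8*HT
    HBLC = np.array([
        _truncnorm(rng, Envelope(env["HBLC"].min, min(env["HBLC"].mean, 0.5 * h),
                                 min(env["HBLC"].max, 0.8 * h), env["HBLC"].sd), ())
        for h in HT
    ])
    CL = HT - HBLC
    trees = pd.DataFrame({
        "tree_id": np.arange(n_trees), "age": ages, "DBH": DBH, "HT": HT,
        "CW": CW, "HBLC": HBLC, "CL": CL, "CR": CL / HT, "HD": HT / DBH,
    })

    # --- primary-branch level --------------------------------------------
    n_branches = _count(rng, config.branches_per_tree, n_trees)
    prim_rows = []
    for t in range(n_trees):
        B = n_branches[t]
        cl_cm = 100.0 * CL[t]
        max_page = min(int(env["PAGE"].max), max(2, round(0.4 * ages[t])))
        for m in range(B):
            r = (m + 1) / (B + 1)  # relative crown depth, tip -> base
            pdinc = np.clip(cl_cm * r * (1 + rng.uniform(-0.08, 0.08)), 1.0, cl_cm)
            page = int(np.clip(round(env["PAGE"].min + r * (max_page - env["PAGE"].min)
                                     + rng.normal(0, 1.0)),
                               env["PAGE"].min, max_page))
            # branch length: unimodal in depth, longest ~3/4 down the crown
            s = (r / 0.78) ** 1.2 * np.exp(1.2 * (1 - r / 0.78))
            pbl_mean = env["PBL"].min + s * (1.17 * env["PBL"].mean - env["PBL"].min)
            pbl = float(_truncnorm(rng, env["PBL"], (), mean=pbl_mean,
                                   sd=0.85 * env["PBL"].sd))
            # diameter: log-linear in length plus noise
            pbd = float(np.exp(-1.168 + 0.83 * np.log(pbl) + rng.normal(0, 0.22)))
            pbd = float(np.clip(pbd, env["PBD"].min, env["PBD"].max))
            pbc = pbl * rng.uniform(0.85, 1.0)
            prim_rows.append((t, m, page, pbl, pbd, pbc,
                              rng.uniform(0, 360), float(_truncnorm(rng, env["PVA"], ())),
                              float(pdinc)))
    primaries = pd.DataFrame(prim_rows, columns=PRIMARY_COLS)

    # --- secondary-branch level ------------------------------------------
    if config.whorls_per_branch == "annual":
        n_whorls = primaries["PAGE"].to_numpy().copy()
    else:
        n_whorls = _count(rng, config.whorls_per_branch, len(primaries))
        # a branch carries at most one whorl per year of its age
        primaries["PAGE"] = np.maximum(primaries["PAGE"], n_whorls)
    n_whorls = np.maximum(n_whorls, 1)

    # exact PSD square root (handles zero and singular covariances)
    evals, evecs = np.linalg.eigh(config.level1_cov)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    sd2 = np.sqrt(config.level2_var)
    sd_e = np.sqrt(config.sigma2)

    sec_rows = []
    eff1_rows = []
    eff2_rows = []
    n_redrawn = 0
    for idx, p in enumerate(primaries.itertuples(index=False)):
        nw = int(n_whorls[idx])
        b_i, c_i = L @ rng.standard_normal(2)
        eff1_rows.append((p.tree_id, p.branch_id, b_i, c_i))
        for j in range(1, nw + 1):
            sdinc_base = j / (nw + 1) * p.PBL
            b_ij = sd2 * rng.standard_normal()
            eff2_rows.append((p.tree_id, p.branch_id, j, b_ij))
            if config.obs_per_whorl == "default":
                n_obs = 1 + rng.poisson(2)
            else:
                n_obs = int(config.obs_per_whorl)
            for k in range(n_obs):
                sdinc = float(np.clip(sdinc_base * (1 + rng.uniform(-0.07, 0.07)),
                                      1e-2, p.PBL))
                mu = float(_response_mean(law, fx, sdinc, p.PDINC, p.PBD,
                                          b_i, c_i, b_ij))
                y = mu + sd_e * rng.standard_normal()
                if config.nonpositive == "redraw":
                    while y <= 0:
                        n_redrawn += 1
                        y = mu + sd_e * rng.standard_normal()
                sec_rows.append((p.tree_id, p.branch_id, j, k, j, sdinc, y, mu))

    sec = pd.DataFrame(
        sec_rows,
        columns=["tree_id", "branch_id", "whorl_id", "obs_id", "SAGE",
                 "SDINC", "_y", "mu"],
    )

    # companion response so both SBL and SBD columns are always present
    comp_law = ("SBD_fixed" if law.startswith("SBL") else "SBL_fixed")
    comp = RESPONSE_LAWS[comp_law]
    merged = sec.merge(primaries[["tree_id", "branch_id", "PDINC", "PBD"]],
                       on=["tree_id", "branch_id"])
    comp_mu = _response_mean(comp_law, comp["fixed_effects"],
                             merged["SDINC"].to_numpy(),
                             merged["PDINC"].to_numpy(), merged["PBD"].to_numpy())
    comp_y = comp_mu + np.sqrt(comp["sigma2"]) * rng.standard_normal(len(sec))
    if law.startswith("SBL"):
        sec["SBL"], sec["SBD"] = sec["_y"], comp_y
    else:
        sec["SBD"], sec["SBL"] = sec["_y"], comp_y
    sec = sec[SECONDARY_COLS + ["mu"]]

    n_total = len(sec) + n_redrawn
    return BranchDataset(
        trees=trees,
        primaries=primaries,
        secondaries=sec,
        provenance=config,
        effects_level1=pd.DataFrame(
            eff1_rows, columns=["tree_id", "branch_id", "b_i", "c_i"]),
        effects_level2=pd.DataFrame(
            eff2_rows, columns=["tree_id", "branch_id", "whorl_id", "b_ij"]),
        rejection_rate=n_redrawn / n_total if n_total else 0.0,
    )


class DatasetParseError(ValueError):
    """Raised when a branch-data file violates the flat schema."""


def write_dataset(dataset: BranchDataset, path) -> None:
    """Write the flat one-row-per-secondary-branch table as CSV (UTF-8)."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path) -> BranchDataset:
    """Read a flat CSV back into the hierarchical container, validating it.

    Checks the schema, numeric parsability, foreign-key resolution and
    the structural invariant 0 < SDINC <= parent PBL, naming offending
    rows in the raised error.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise DatasetParseError(f"missing column(s): {', '.join(missing)}")
    for col in SCHEMA:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()].tolist()[:5]
            raise DatasetParseError(
                f"non-numeric value in column {col!r}, rows {bad}") from exc
    bad = df.index[(df["SDINC"] <= 0) | (df["SDINC"] > df["PBL"] * (1 + 1e-9))]
    if len(bad):
        raise DatasetParseError(
            f"SDINC outside (0, PBL] at rows {bad.tolist()[:10]}")
    trees = df[TREE_COLS].drop_duplicates("tree_id").reset_index(drop=True)
    primaries = (df[PRIMARY_COLS]
                 .drop_duplicates(["tree_id", "branch_id"]).reset_index(drop=True))
    secondaries = df[SECONDARY_COLS].reset_index(drop=True)
    return BranchDataset(trees=trees, primaries=primaries,
                         secondaries=secondaries, provenance=str(path))
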