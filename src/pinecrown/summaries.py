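"""Descriptive crown-profile statistics for secondary branches.

Whorl-wise and age-group mean sizes, current-year shoot summaries, and
the relative depth at which the mean size profile peaks along the
primary branch. Mean secondary-branch size rises from the branch tip
inward and then falls toward the branch base; the peak sits around
three quarters of the way down.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pinecrown.growth import ModelSpec, interior_maximum
from pinecrown.synth import BranchDataset

__all__ = [
    "AGE_CLASSES",
    "whorl_means",
    "current_year_shoots",
    "inflection_point",
]

#: even-aged stand classes of the sampled plantation, years
AGE_CLASSES = (28, 40, 46, 53, 64, 70)

#: number of equal relative-depth (SDINC/PBL) bins
N_DEPTH_BINS = 10


def _flat(dataset) -> pd.DataFrame:
    if isinstance(dataset, BranchDataset):
        return dataset.to_frame()
    return dataset


def whorl_means(dataset, by: str = "SAGE") -> pd.DataFrame:
    """Mean size of secondary branches per group, tip-first ordering.

    ``by``: 'SAGE' (whorl age of the secondary branch), 'PAGE'
    (primary-branch age) or 'depth' (10 equal bins of relative depth
    SDINC/PBL). Also splits by stand age class. Returns columns
    ``age, group, mean_SBL, mean_SBD, sd_SBL, sd_SBD, n``.
    """
    df = _flat(dataset)
    if df.empty:
        raise ValueError("empty dataset")
    if by == "depth":
        rel = df["SDINC"] / df["PBL"]
        edges = np.linspace(0, 1, N_DEPTH_BINS + 1)
        df = df.assign(group=pd.cut(rel, edges, include_lowest=True,
                                    labels=np.round(
                                        (edges[:-1] + edges[1:]) / 2, 3)))
    elif by in ("SAGE", "PAGE"):
        df = df.assign(group=df[by])
    else:
        raise ValueError("by must be 'SAGE', 'PAGE' or 'depth'")
    out = (df.groupby(["age", "group"], observed=True)
             .agg(mean_SBL=("SBL", "mean"), mean_SBD=("SBD", "mean"),
                  sd_SBL=("SBL", "std"), sd_SBD=("SBD", "std"),
                  n=("SBL", "size"))
             .reset_index())
    return out.sort_values(["age", "group"]).reset_index(drop=True)


def current_year_shoots(dataset) -> pd.DataFrame:
    """Mean size of newly germinated shoots (SAGE = 1) against the age
    of the carrying primary branch. Empty frame when none exist."""
    df = _flat(dataset)
    sub = df[df["SAGE"] == 1]
    if sub.empty:
        return pd.DataFrame(columns=["PAGE", "mean_SBL", "mean_SBD", "n"])
    out = (sub.groupby("PAGE")
              .agg(mean_SBL=("SBL", "mean"), mean_SBD=("SBD", "mean"),
                   n=("SBL", "size"))
              .reset_index())
    return out.sort_values("PAGE").reset_index(drop=True)


def inflection_point(dataset=None, measure: str = "length",
                     method: str = "binned",
                     params: dict | None = None,
                     branch_length: float | None = None):
    """Relative depth in (0, 1] at which the mean size profile peaks.

    ``method='binned'``: argmax of the 10-bin relative-depth mean
    profile (bin midpoint). ``method='fitted'``: peak of a fitted or
    supplied Roeecp curve, b/c, capped at the branch length and
    expressed relative to it (averaged over branches when a dataset is
    given). A monotonically increasing profile returns 1.0 with
    ``flagged=True``. Returns ``(relative_depth, flagged)``.
    """
    col = "SBL" if measure == "length" else "SBD"
    if method == "fitted":
        if params is None:
            raise ValueError("method='fitted' needs Roeecp params (b, c)")
        peak = interior_maximum(ModelSpec("M7"),
                                {"a": params.get("a", 1.0),
                                 "b": params["b"], "c": params["c"]})
        if branch_length is not None:
            lengths = np.asarray([branch_length], dtype=float)
        elif dataset is not None:
            lengths = _flat(dataset).groupby(
                ["tree_id", "branch_id"])["PBL"].first().to_numpy()
        else:
            raise ValueError("need branch_length or dataset")
        if peak is None:
            return 1.0, True
        rel = np.minimum(peak / lengths, 1.0)
        return float(np.mean(rel)), bool(np.all(peak >= lengths))
    if method != "binned":
        raise ValueError("method must be 'binned' or 'fitted'")
    df = _flat(dataset)
    rel = (df["SDINC"] / df["PBL"]).to_numpy()
    edges = np.linspace(0, 1, N_DEPTH_BINS + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(rel, edges[1:-1]), 0, N_DEPTH_BINS - 1)
    sums = np.bincount(which, weights=df[col].to_numpy(),
                       minlength=N_DEPTH_BINS)
    cnts = np.bincount(which, minlength=N_DEPTH_BINS)
    with np.errstate(invalid="ignore"):
        prof = sums / cnts
    valid = cnts > 0
    if not valid.any():
        raise ValueError("empty dataset")
    vprof = prof[valid]
    vmids = mids[valid]
    k = int(np.nanargmax(vprof))
    flagged = bool(k == len(vprof) - 1 and np.all(np.diff(vprof) >= 0))
    if flagged:
        return 1.0, True
    return float(vmids[k]), False
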