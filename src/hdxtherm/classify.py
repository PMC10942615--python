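"""Dynamic-group classification of peptides from D% uptake curves.

Peptides are partitioned into four dynamic groups by how much they exchange
(D%, relative to the theoretic maximum) and how they respond to binding:

* III — highly dynamic: D% of both states already above a cutoff (default
  60%) at the first timepoint; the binder affords at most weak protection.
* IV  — solvent-exposed but deprotected: free-state D% inside a medium band
  (default 40-50%) at every timepoint, with significant deprotection
  (delta > 0) at >= 1 timepoint (allosteric loosening).
* I   — strongly protected: significant protection at every timepoint and
  bound-state D% below a low cutoff (default 10%) throughout — i.e. binding
  essentially halts exchange for the whole time course.
* II  — progressively exchanging, protected: rising free-state uptake with
  significant protection at >= 1 timepoint.

Precedence III -> IV -> I -> II: the absolute-uptake bands are the more
specific conditions; protection-defined groups catch the remainder.  All
cutoffs are parameters with strict inequality at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("I", "II", "III", "IV", "unassigned")


@dataclass(frozen=True)
class ClassificationParams:
    fast_d_percent_at_30s: float = 5.0
    group3_d_percent: float = 60.0
    group4_band: tuple[float, float] = (40.0, 50.0)
    group1_bound_max_d_percent: float = 10.0

    def __post_init__(self) -> None:
        values = (
            self.fast_d_percent_at_30s,
            self.group3_d_percent,
            *self.group4_band,
            self.group1_bound_max_d_percent,
        )
        if any(not 0 <= v <= 100 for v in values):
            raise ValueError("classification cutoffs must be in [0, 100]")


def classify_peptides(
    curves: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Assign one dynamic-group label per peptide.

    ``curves`` needs one row per peptide x timepoint with columns start,
    end, timepoint_s, dpct_free, dpct_bound, significant, direction.
    Returns one row per peptide: start, end, group.
    """
    params = params or ClassificationParams()
    required = {"start", "end", "timepoint_s", "dpct_free", "dpct_bound",
                "significant", "direction"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table missing columns {sorted(missing)}")

    lo4, hi4 = params.group4_band
    out = []
    for (start, end), grp in curves.groupby(["start", "end"], sort=True):
        grp = grp.sort_values("timepoint_s")
        if grp["timepoint_s"].duplicated().any():
            raise ValueError(f"duplicate timepoints for peptide ({start}, {end})")
        free = grp["dpct_free"].to_numpy(float)
        bound = grp["dpct_bound"].to_numpy(float)
        prot = (grp["significant"] & (grp["direction"] == "protected")).to_numpy()
        deprot = (grp["significant"] & (grp["direction"] == "deprotected")).to_numpy()

        if free[0] >= params.group3_d_percent and bound[0] >= params.group3_d_percent:
            group = "III"
        elif np.all((free >= lo4) & (free <= hi4)) and deprot.any():
            group = "IV"
        elif prot.all() and np.all(bound <= params.group1_bound_max_d_percent):
            group = "I"
        elif prot.any() and np.all(np.diff(free) > 0):
            group = "II"
        else:
            group = "unassigned"
        out.append({"start": start, "end": end, "group": group})
    return pd.DataFrame(out)


def flag_fast_exchangers(
    curves: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Flag peptides whose free-state D% exceeds the cutoff (default 5%,
    strict) at the first timepoint."""
    params = params or ClassificationParams()
    first_t = curves["timepoint_s"].min()
    first = curves[curves["timepoint_s"] == first_t]
    out = first[["start", "end"]].copy()
    out["fast_exchanger"] = (
        first["dpct_free"] > params.fast_d_percent_at_30s
    ).to_numpy()
    return out.sort_values(["start", "end"]).reset_index(drop=True)


def classification_table(
    curves: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Joined classification output: start, end, group, fast_exchanger."""
    groups = classify_peptides(curves, params)
    fast = flag_fast_exchangers(curves, params)
    return groups.merge(fast, on=["start", "end"])


def uptake_percent_curves(
    deltas: pd.DataFrame, pmap
) -> pd.DataFrame:
    """Build the D% curves table from differential records and a map.

    Converts the per-cell state means to percent of each peptide's
    theoretic maximum; peptides with n_max = 0 are dropped (D% undefined).
    """
    n_max = {(p.start, p.end): p.n_max for p in pmap.peptides}
    rows = deltas[
        ["start", "end", "timepoint_s", "mean_free", "mean_bound",
         "significant", "direction"]
    ].copy()
    rows["n_max"] = [
        n_max.get((s, e), 0) for s, e in zip(rows["start"], rows["end"])
    ]
    rows = rows[rows["n_max"] > 0]
    rows["dpct_free"] = 100.0 * rows["mean_free"] / rows["n_max"]
    rows["dpct_bound"] = 100.0 * rows["mean_bound"] / rows["n_max"]
    return rows.drop(columns=["mean_free", "mean_bound", "n_max"])
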