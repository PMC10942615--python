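"""Differential uptake between states and hybrid significance testing.

The state difference for each peptide x timepoint cell is
``delta = D_bound - D_free`` (delta < 0 = protection, delta > 0 =
deprotection).  A cell is called significant by the hybrid criterion when
both conditions hold:

* ``|delta| >= T``, where the global threshold
  ``T = t_crit(1 - alpha/2, df) * s_pooled * sqrt(1/n_free + 1/n_bound)``
  derives from the pooled replicate standard deviation across all cells; and
* a per-cell Welch's t-test gives ``p <= alpha_ttest``.

The conjunction of a magnitude filter and a per-cell test is the standard
hybrid criterion for peptide-level differential HDX; it is conservative
relative to either test alone.  Both alphas are configurable, and a manual
threshold override lets a published threshold be replayed on any data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PEPTIDE_KEYS = ["start", "end", "sequence"]
CELL_KEYS = PEPTIDE_KEYS + ["timepoint_s"]


@dataclass(frozen=True)
class HybridParams:
    """Realized parameters of the hybrid criterion."""

    s_pooled: float
    df_pooled: float
    alpha_global: float
    alpha_ttest: float
    threshold: float


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Per peptide x state x timepoint mean, sample sd (n-1) and n.

    Cells with fewer than 2 replicates are excluded and logged.
    """
    if table.empty:
        raise ValueError("empty uptake table")
    grouped = (
        table.groupby(CELL_KEYS + ["state"], as_index=False)["uptake_da"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    )
    thin = grouped["n"] < 2
    if thin.any():
        for _, row in grouped[thin].iterrows():
            logger.warning(
                "excluding cell (%s-%s, %s, t=%s) with n=%d < 2",
                row["start"], row["end"], row["state"],
                row["timepoint_s"], row["n"],
            )
        grouped = grouped[~thin].reset_index(drop=True)
    if grouped.empty:
        raise ValueError("no cell has >= 2 replicates")
    grouped["sd"] = grouped["sd"].fillna(0.0)
    return grouped


def pooled_sd(*summaries: pd.DataFrame) -> tuple[float, float]:
    """Pooled replicate sd and df over all cells of all given summaries.

    s_pooled = sqrt( sum (n_c - 1) sd_c^2 / sum (n_c - 1) );
    df_pooled = sum (n_c - 1).
    """
    cells = pd.concat(summaries, ignore_index=True)
    df_c = cells["n"] - 1
    df_pooled = float(df_c.sum())
    if df_pooled <= 0:
        raise ValueError("no replicate degrees of freedom to pool")
    s2 = float((df_c * cells["sd"] ** 2).sum() / df_pooled)
    return float(np.sqrt(s2)), df_pooled


def global_threshold(
    s_pooled: float,
    df_pooled: float,
    n_free: int,
    n_bound: int,
    alpha_global: float = 0.05,
) -> float:
    """Magnitude threshold T (Da) for the hybrid criterion."""
    if s_pooled < 0:
        raise ValueError("s_pooled must be >= 0")
    if df_pooled <= 0:
        raise ValueError("df_pooled must be > 0")
    if not (0 < alpha_global < 1):
        raise ValueError("alpha_global must be in (0, 1)")
    t_crit = stats.t.ppf(1 - alpha_global / 2, df_pooled)
    return float(t_crit * s_pooled * np.sqrt(1.0 / n_free + 1.0 / n_bound))


def welch_ttest(reps_free, reps_bound) -> tuple[float, float, float]:
    """Welch's two-sample t-test (Satterthwaite df, two-sided p).

    Zero variance in both groups with equal means returns (0, df, 1).
    """
    a = np.asarray(reps_free, dtype=float)
    b = np.asarray(reps_bound, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    t, df, p = _welch_arrays(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
    return float(t), float(df), float(p)


def _welch_arrays(mean1, sd1, n1, mean2, sd2, n2):
    """Vectorized Welch statistic/df/p from per-group summaries.

    Degenerate cells (zero variance in both groups): t = 0, p = 1 for equal
    means; |t| = inf, p = 0 otherwise.
    """
    mean1, sd1 = np.asarray(mean1, float), np.asarray(sd1, float)
    mean2, sd2 = np.asarray(mean2, float), np.asarray(sd2, float)
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    denom2 = v1 + v2
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = denom2 == 0
    t = np.where(zero, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)), t)
    p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    df = np.where(zero, np.asarray(n1) + np.asarray(n2) - 2.0, df)
    return t, df, p


def delta_uptake(
    free_table: pd.DataFrame, bound_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell state difference records (bound - free) with Welch's test.

    Input order of peptides is preserved (peptide_index) so residual plots
    of delta vs peptide index per timepoint can be drawn directly.
    Cells present in only one state are excluded and logged.
    ``sum_delta_da`` is the per-peptide sum of delta over all timepoints.
    """
    free = summarize_cells(free_table)
    bound = summarize_cells(bound_table)
    merged = free.merge(
        bound, on=CELL_KEYS, suffixes=("_free", "_bound"), how="outer",
        indicator=True,
    )
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        for _, row in merged[unmatched].iterrows():
            logger.warning(
                "excluding unmatched cell (%s-%s, t=%s): present in %s only",
                row["start"], row["end"], row["timepoint_s"],
                "free" if row["_merge"] == "left_only" else "bound",
            )
        merged = merged[~unmatched]
    if merged.empty:
        raise ValueError("no matched peptide x timepoint cells")
    merged = merged.drop(columns="_merge").reset_index(drop=True)

    order = (
        free_table[PEPTIDE_KEYS].drop_duplicates().reset_index(drop=True)
    )
    order["peptide_index"] = np.arange(1, len(order) + 1)
    merged = merged.merge(order, on=PEPTIDE_KEYS, how="left")
    merged = merged.sort_values(
        ["peptide_index", "timepoint_s"]
    ).reset_index(drop=True)

    merged["delta"] = merged["mean_bound"] - merged["mean_free"]
    t, df, p = _welch_arrays(
        merged["mean_bound"], merged["sd_bound"], merged["n_bound"].to_numpy(),
        merged["mean_free"], merged["sd_free"], merged["n_free"].to_numpy(),
    )
    merged["welch_t"] = t
    merged["welch_df"] = df
    merged["welch_p"] = p
    merged["sum_delta"] = merged.groupby(PEPTIDE_KEYS)["delta"].transform(
        "sum"
    )
    return merged


def hybrid_significance(
    deltas: pd.DataFrame, params: HybridParams
) -> pd.DataFrame:
    """Apply the hybrid criterion; adds significant / direction columns.

    significant iff |delta| >= threshold AND welch_p <= alpha_ttest;
    direction is protected for significant delta < 0, deprotected for
    significant delta > 0, none otherwise.
    """
    out = deltas.copy()
    out["significant"] = (np.abs(out["delta"]) >= params.threshold) & (
        out["welch_p"] <= params.alpha_ttest
    )
    out["direction"] = np.select(
        [out["significant"] & (out["delta"] < 0),
         out["significant"] & (out["delta"] > 0)],
        ["protected", "deprotected"],
        default="none",
    )
    return out


def differential_analysis(
    free_table: pd.DataFrame,
    bound_table: pd.DataFrame,
    alpha_global: float = 0.05,
    alpha_ttest: float = 0.05,
    threshold_override: float | None = None,
    threshold_df: str = "pooled",
) -> tuple[pd.DataFrame, HybridParams]:
    """Full differential pipeline: summarize -> delta -> hybrid flags.

    ``threshold_df`` selects the degrees of freedom for the global
    threshold's t quantile: "pooled" uses the summed replicate df across all
    cells (large-sample, near-normal quantile); "per_comparison" uses
    n_free + n_bound - 2 of a single cell, which with triplicates gives the
    ~0.3 Da thresholds familiar from published membrane-protein studies.
    """
    free = summarize_cells(free_table)
    bound = summarize_cells(bound_table)
    s_pooled, df_pooled = pooled_sd(free, bound)
    n_free = int(free["n"].mode().iat[0])
    n_bound = int(bound["n"].mode().iat[0])
    if threshold_df == "pooled":
        df_t = df_pooled
    elif threshold_df == "per_comparison":
        df_t = float(n_free + n_bound - 2)
    else:
        raise ValueError("threshold_df must be 'pooled' or 'per_comparison'")
    if threshold_override is not None:
        threshold = float(threshold_override)
    elif s_pooled == 0:
        threshold = 0.0
    else:
        threshold = global_threshold(
            s_pooled, df_t, n_free, n_bound, alpha_global
        )
    params = HybridParams(
        s_pooled=s_pooled,
        df_pooled=df_pooled,
        alpha_global=alpha_global,
        alpha_ttest=alpha_ttest,
        threshold=threshold,
    )
    deltas = delta_uptake(free_table, bound_table)
    return hybrid_significance(deltas, params), params


def write_residual_csv(deltas: pd.DataFrame, path) -> None:
    """Residual-plot table: delta vs peptide index per timepoint."""
    cols = deltas[
        ["peptide_index", "start", "end", "timepoint_s", "delta",
         "sum_delta", "welch_p", "significant", "direction"]
    ].rename(
        columns={"delta": "delta_da", "sum_delta": "sum_delta_da"}
    )
    cols = cols.copy()
    cols["delta_da"] = cols["delta_da"].map(lambda v: f"{v:.4f}")
    cols["sum_delta_da"] = cols["sum_delta_da"].map(lambda v: f"{v:.4f}")
    cols["welch_p"] = cols["welch_p"].map(lambda v: f"{v:.3e}")
    cols.to_csv(path, index=False)
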