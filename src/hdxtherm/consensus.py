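"""Peptide-to-residue consensus mapping and structure annotation.

Peptide-level significance calls are projected onto residues through the
overlapping peptides that observe them.  A residue's contributing peptides
are those whose observable amide positions (start+1..end, prolines
excluded) include it; the consensus rule (any / majority / all) then
decides the residue's status from the contributors' flags.  Direction
conflicts resolve to "protected" (protection dominates differential HDX of
binder-trapped states) and are logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .peptides import PeptideMap

logger = logging.getLogger(__name__)

STATUSES = ("protected", "deprotected", "insignificant", "uncovered")
_SENTINEL_B = -99.0


def map_significance_to_residues(
    deltas: pd.DataFrame,
    pmap: PeptideMap,
    timepoint: float,
    rule: str = "any",
) -> pd.DataFrame:
    """Per-residue status map at one timepoint.

    Returns a DataFrame with one row per construct position: position,
    display_position, status, n_peptides (contributing peptides) and
    mean_delta_da over contributors.
    """
    if rule not in ("any", "majority", "all"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    at_t = deltas[deltas["timepoint_s"] == timepoint]
    if at_t.empty:
        raise ValueError(f"no delta records at timepoint {timepoint}")
    flags = {
        (row["start"], row["end"]): (row["significant"], row["direction"],
                                     row["delta"])
        for _, row in at_t.iterrows()
    }

    length = len(pmap.protein)
    n_pep = np.zeros(length + 1, dtype=int)
    n_sig_prot = np.zeros(length + 1, dtype=int)
    n_sig_deprot = np.zeros(length + 1, dtype=int)
    delta_sum = np.zeros(length + 1)

    for pep in pmap.peptides:
        key = (pep.start, pep.end)
        if key not in flags:
            continue
        significant, direction, delta = flags[key]
        for pos in pep.amide_positions():
            n_pep[pos] += 1
            delta_sum[pos] += delta
            if significant and direction == "protected":
                n_sig_prot[pos] += 1
            elif significant and direction == "deprotected":
                n_sig_deprot[pos] += 1

    rows = []
    for pos in range(1, length + 1):
        n = n_pep[pos]
        if n == 0:
            status = "uncovered"
            mean_delta = np.nan
        else:
            mean_delta = delta_sum[pos] / n
            n_sig = n_sig_prot[pos] + n_sig_deprot[pos]
            if rule == "any":
                hit = n_sig >= 1
            elif rule == "majority":
                hit = n_sig > n / 2
            else:  # all
                hit = n_sig == n
            if not hit:
                status = "insignificant"
            elif n_sig_prot[pos] and n_sig_deprot[pos]:
                logger.warning(
                    "direction conflict at position %d "
                    "(%d protected vs %d deprotected peptides); "
                    "protected wins",
                    pos, n_sig_prot[pos], n_sig_deprot[pos],
                )
                status = "protected"
            elif n_sig_prot[pos]:
                status = "protected"
            else:
                status = "deprotected"
        rows.append(
            {
                "position": pos,
                "display_position": pmap.protein.display_position(pos),
                "status": status,
                "n_peptides": int(n),
                "mean_delta_da": mean_delta,
            }
        )
    return pd.DataFrame(rows)


def position_counts(statusmap: pd.DataFrame) -> dict[str, int]:
    """Counts per status; always sums to the protein length."""
    counts = statusmap["status"].value_counts().to_dict()
    return {status: int(counts.get(status, 0)) for status in STATUSES}


def write_residue_tsv(statusmap: pd.DataFrame, path) -> None:
    out = statusmap.copy()
    out["mean_delta_da"] = out["mean_delta_da"].map(
        lambda v: "" if pd.isna(v) else f"{v:.4f}"
    )
    out.to_csv(path, sep="\t", index=False)


def write_structure_annotation(
    statusmap: pd.DataFrame,
    structure_path,
    out_path,
    value: str = "mean_delta_da",
    structure_offset: int = 0,
) -> int:
    """Write a per-residue value into the B-factor column of a structure.

    ``value`` is either "mean_delta_da" or "status" (status codes:
    protected -1, deprotected +1, insignificant 0); residues of the
    structure with no matching construct position get the sentinel -99.
    Structure residue numbering is reconciled with construct numbering via
    ``display_position + structure_offset``.  Returns the number of matched
    residues.
    """
    import gemmi

    if value not in ("mean_delta_da", "status"):
        raise ValueError("value must be 'mean_delta_da' or 'status'")
    status_code = {"protected": -1.0, "deprotected": 1.0,
                   "insignificant": 0.0, "uncovered": _SENTINEL_B}
    lookup: dict[int, float] = {}
    for _, row in statusmap.iterrows():
        seqid = int(row["display_position"]) + structure_offset
        if value == "status":
            lookup[seqid] = status_code[row["status"]]
        else:
            v = row["mean_delta_da"]
            lookup[seqid] = (
                _SENTINEL_B
                if row["status"] == "uncovered" or pd.isna(v)
                else float(v)
            )

    structure = gemmi.read_structure(str(structure_path))
    matched = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                b = lookup.get(residue.seqid.num, _SENTINEL_B)
                if residue.seqid.num in lookup:
                    matched += 1
                for atom in residue:
                    atom.b_iso = b
    if matched == 0:
        raise ValueError(
            f"no residue of {structure_path} matched the construct numbering"
        )
    out_path = str(out_path)
    if out_path.endswith(".cif"):
        structure.make_mmcif_document().write_file(out_path)
    else:
        structure.write_pdb(out_path)
    return matched


def brute_force_residue_status(
    deltas: pd.DataFrame,
    pmap: PeptideMap,
    timepoint: float,
    rule: str = "any",
) -> list[str]:
    """Independent per-position enumeration of residue statuses.

    Reference oracle: for every position, scan every peptide and test
    membership in its amide positions directly, then apply the rule.  Kept
    deliberately naive and separate from the production mapping path.
    """
    at_t = deltas[deltas["timepoint_s"] == timepoint]
    statuses = []
    for pos in range(1, len(pmap.protein) + 1):
        contributors = []
        for pep in pmap.peptides:
            if pos in pep.amide_positions():
                rec = at_t[(at_t["start"] == pep.start)
                           & (at_t["end"] == pep.end)]
                if len(rec):
                    contributors.append(rec.iloc[0])
        if not contributors:
            statuses.append("uncovered")
            continue
        sig = [c for c in contributors if c["significant"]]
        n, k = len(contributors), len(sig)
        hit = {"any": k >= 1, "majority": k > n / 2, "all": k == n}[rule]
        if not hit:
            statuses.append("insignificant")
        elif any(c["direction"] == "protected" for c in sig):
            statuses.append("protected")
        else:
            statuses.append("deprotected")
    return statuses
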