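#!/usr/bin/env python
"""Map peptide-level significance onto residues at the late timepoint.

Applies the consensus rule (any significant covering peptide sets the
status) at 3000 s, writes the per-residue TSV and reports the recovered
protected block against the simulation's ground-truth footprint.
"""

from pathlib import Path

import pandas as pd

from hdxtherm.consensus import (
    map_significance_to_residues,
    position_counts,
    write_residue_tsv,
)
from hdxtherm.differential import differential_analysis
from hdxtherm.io import read_uptake_csv, peptide_map_from_table
from hdxtherm.peptides import read_fasta

OUTDIR = Path("results/hdx")
TIMEPOINT = 3000.0


def main() -> None:
    protein = read_fasta(OUTDIR / "construct.fasta")
    free = read_uptake_csv(OUTDIR / "uptake_free.csv", protein)
    bound = read_uptake_csv(OUTDIR / "uptake_bound.csv", protein)
    pmap = peptide_map_from_table(free, protein)
    deltas, _ = differential_analysis(free, bound)

    status = map_significance_to_residues(deltas, pmap, TIMEPOINT, rule="any")
    write_residue_tsv(status, OUTDIR / "residues.tsv")
    counts = position_counts(status)
    print(f"consensus at {TIMEPOINT:.0f} s (rule: any): " +
          ", ".join(f"{k} {v}" for k, v in counts.items()))

    truth = pd.read_csv(OUTDIR / "ground_truth.csv")
    fp = set(truth.loc[truth["footprint"] == "protected", "residue"])
    mapped = set(status.loc[status["status"] == "protected", "position"])
    overlap = len(mapped & fp) / len(fp)
    print(f"true footprint {min(fp)}-{max(fp)} ({len(fp)} residues); "
          f"{len(mapped & fp)} recovered ({overlap:.0%} overlap), "
          f"{len(mapped - fp)} called outside it")
    print(f"per-residue table written to {OUTDIR / 'residues.tsv'}")


if __name__ == "__main__":
    main()
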