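#!/usr/bin/env python
"""Classify peptides into dynamic groups and flag fast exchangers.

Builds D% uptake curves (percent of the theoretic maximum) for both states,
assigns each peptide to one of the four dynamic groups (I strongly
protected, II rising-with-protection, III highly dynamic, IV mid-band
deprotected) and flags fast exchangers (>5% free-state D% at 30 s).
Writes results/hdx/classification.csv.
"""

from pathlib import Path

from hdxtherm.classify import classification_table, uptake_percent_curves
from hdxtherm.differential import differential_analysis
from hdxtherm.io import read_uptake_csv, peptide_map_from_table
from hdxtherm.peptides import read_fasta

OUTDIR = Path("results/hdx")


def main() -> None:
    protein = read_fasta(OUTDIR / "construct.fasta")
    free = read_uptake_csv(OUTDIR / "uptake_free.csv", protein)
    bound = read_uptake_csv(OUTDIR / "uptake_bound.csv", protein)
    pmap = peptide_map_from_table(free, protein)
    deltas, _ = differential_analysis(free, bound)

    curves = uptake_percent_curves(deltas, pmap)
    table = classification_table(curves)
    table.to_csv(OUTDIR / "classification.csv", index=False)

    tallies = table["group"].value_counts().to_dict()
    print("dynamic groups: " + ", ".join(
        f"{g}: {tallies.get(g, 0)}" for g in ("I", "II", "III", "IV",
                                              "unassigned")))
    print(f"fast exchangers (>5% D% at 30 s): "
          f"{int(table['fast_exchanger'].sum())}/{len(table)} peptides")
    print(f"classification written to {OUTDIR / 'classification.csv'}")


if __name__ == "__main__":
    main()
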