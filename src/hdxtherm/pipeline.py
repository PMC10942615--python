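"""End-to-end differential HDX pipeline driver.

Runs simulate (optional) -> summarize -> delta -> hybrid flags ->
residue consensus -> dynamic-group classification -> optional structure
annotation, writing the residual-plot CSV, per-residue TSV, classification
CSV and a machine-readable summary JSON (pooled sd, threshold, status
counts, group tallies, config echo, config hash and seed) into the output
directory.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import classify as classify_mod
from . import consensus as consensus_mod
from . import differential, io, simulate
from .peptides import coverage_stats

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    try:
        if config.simulate:
            truth = simulate.simulate_system(
                length=config.protein_length, seed=config.seed
            )
            pmap = simulate.simulate_digestion(truth.protein, seed=config.seed)
            design = simulate.ExperimentDesign(
                timepoints=config.timepoints,
                n_replicates=config.n_replicates,
                noise_sd=config.noise_sd,
                states=config.states,
                seed=config.seed,
            )
            free_table, bound_table = simulate.simulate_uptake_tables(
                truth, pmap, design
            )
            io.write_uptake_csv(free_table, outdir / "uptake_free.csv")
            io.write_uptake_csv(bound_table, outdir / "uptake_bound.csv")
            simulate.write_ground_truth_csv(truth, outdir / "ground_truth.csv")
            protein = truth.protein
        else:
            protein = (
                None
                if config.fasta_path is None
                else __import__(
                    "hdxtherm.peptides", fromlist=["read_fasta"]
                ).read_fasta(config.fasta_path)
            )
            free_table = io.read_uptake_csv(config.free_csv, protein)
            bound_table = io.read_uptake_csv(config.bound_csv, protein)
            if protein is None:
                raise ValueError(
                    "fasta_path is required to analyze external tables"
                )
            pmap = io.peptide_map_from_table(free_table, protein)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError("load", exc) from exc

    try:
        deltas, params = differential.differential_analysis(
            free_table,
            bound_table,
            alpha_global=config.alpha_global,
            alpha_ttest=config.alpha_ttest,
            threshold_override=config.threshold_override,
            threshold_df=config.threshold_df,
        )
        differential.write_residual_csv(deltas, outdir / "residuals.csv")
    except Exception as exc:
        raise StageError("differential", exc) from exc

    try:
        statusmap = consensus_mod.map_significance_to_residues(
            deltas, pmap, config.consensus_timepoint, config.consensus_rule
        )
        counts = consensus_mod.position_counts(statusmap)
        consensus_mod.write_residue_tsv(statusmap, outdir / "residues.tsv")
    except Exception as exc:
        raise StageError("consensus", exc) from exc

    try:
        cls_params = classify_mod.ClassificationParams(**config.classification)
        curves = classify_mod.uptake_percent_curves(deltas, pmap)
        table = classify_mod.classification_table(curves, cls_params)
        table.to_csv(outdir / "classification.csv", index=False)
        group_tallies = table["group"].value_counts().to_dict()
        n_fast = int(table["fast_exchanger"].sum())
    except Exception as exc:
        raise StageError("classify", exc) from exc

    annotated = None
    if config.structure_path is not None:
        try:
            out_structure = outdir / "annotated.pdb"
            consensus_mod.write_structure_annotation(
                statusmap, config.structure_path, out_structure
            )
            annotated = str(out_structure)
        except Exception as exc:
            raise StageError("annotate", exc) from exc

    stats = coverage_stats(pmap)
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_peptides": stats.n_peptides,
        "coverage_percent": round(stats.coverage_percent, 4),
        "redundancy": round(stats.redundancy, 4),
        "mean_peptide_length": round(stats.mean_peptide_length, 4),
        "s_pooled_da": round(params.s_pooled, 6),
        "df_pooled": params.df_pooled,
        "threshold_da": round(params.threshold, 6),
        "n_significant_cells": int(deltas["significant"].sum()),
        "position_counts": counts,
        "group_tallies": {g: int(group_tallies.get(g, 0))
                          for g in classify_mod.GROUPS},
        "n_fast_exchangers": n_fast,
        "annotated_structure": annotated,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
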