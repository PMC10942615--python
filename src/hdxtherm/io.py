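"""File-format dialects and run configuration shared by all stages.

Formats: single-record FASTA for the construct; an uptake CSV with one row
per peptide x state x timepoint x replicate; a thermogram CSV with
``#``-prefixed metadata lines; YAML run configuration.  All floating-point
outputs use fixed precision (uptake 4 decimals, p-values 3 significant
digits) so outputs diff cleanly across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .itc import Thermogram, TitrationSchedule
from .peptides import PeptideMap, ProteinSequence, build_peptide_map

UPTAKE_HEADER = [
    "protein_id", "start", "end", "sequence", "state", "timepoint_s",
    "replicate", "uptake_da",
]


def read_uptake_csv(path, protein: ProteinSequence | None = None) -> pd.DataFrame:
    """Read and validate an uptake table.

    Malformed rows are rejected with their line number; when a construct is
    given, every peptide sequence/range is checked against it.
    """
    table = pd.read_csv(path)
    if list(table.columns) != UPTAKE_HEADER:
        raise ValueError(
            f"{path}: bad header {list(table.columns)}, expected {UPTAKE_HEADER}"
        )
    for idx, row in table.iterrows():
        lineno = idx + 2
        try:
            start, end = int(row["start"]), int(row["end"])
            timepoint = float(row["timepoint_s"])
            uptake = float(row["uptake_da"])
            int(row["replicate"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row") from exc
        if end < start or start < 1:
            raise ValueError(
                f"{path}:{lineno}: bad peptide range ({start}, {end})"
            )
        if timepoint <= 0:
            raise ValueError(f"{path}:{lineno}: timepoint must be > 0")
        if uptake < 0:
            raise ValueError(f"{path}:{lineno}: negative uptake")
        if len(str(row["sequence"])) != end - start + 1:
            raise ValueError(
                f"{path}:{lineno}: sequence length does not match range"
            )
        if protein is not None:
            expected = protein.sequence[start - 1 : end]
            if str(row["sequence"]) != expected:
                raise ValueError(
                    f"{path}:{lineno}: sequence {row['sequence']!r} does not "
                    f"match construct at ({start}, {end})"
                )
    dup = table.duplicated(
        ["start", "end", "sequence", "state", "timepoint_s", "replicate"]
    )
    if dup.any():
        raise ValueError(
            f"{path}:{int(dup.idxmax()) + 2}: duplicate replicate index"
        )
    return table


def write_uptake_csv(table: pd.DataFrame, path) -> None:
    out = table[UPTAKE_HEADER].copy()
    out["uptake_da"] = out["uptake_da"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, index=False)


def peptide_map_from_table(
    table: pd.DataFrame, protein: ProteinSequence
) -> PeptideMap:
    """Induce the peptide map from the distinct (start, end) of a table."""
    ranges = (
        table[["start", "end"]].drop_duplicates().itertuples(index=False)
    )
    return build_peptide_map(protein, [(r.start, r.end) for r in ranges])


def write_thermogram_csv(thermogram: Thermogram, path) -> None:
    """Thermogram CSV: metadata header lines then injection,dv_ul,heat."""
    sched = thermogram.schedule
    sign = "exothermic_positive" if thermogram.exothermic_positive else \
        "exothermic_negative"
    with open(path, "w") as fh:
        fh.write(f"# v0_ul={sched.v0_ul:g}\n")
        fh.write(f"# syringe_um={sched.syringe_um:g}\n")
        fh.write(f"# cell_um={sched.cell_um:g}\n")
        fh.write(f"# temperature_c={sched.temperature_c:g}\n")
        fh.write(f"# sign={sign}\n")
        fh.write("injection,dv_ul,heat\n")
        for i, (dv, q) in enumerate(
            zip(sched.injection_volumes_ul, thermogram.heats_ucal), start=1
        ):
            fh.write(f"{i},{dv:g},{q:.6f}\n")


def read_thermogram_csv(path) -> Thermogram:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("injection,"):
                rows.append(line.split(","))
    required = {"v0_ul", "syringe_um", "cell_um", "sign"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"{path}: missing metadata {sorted(missing)}")
    dv = tuple(float(r[1]) for r in rows)
    heats = np.array([float(r[2]) for r in rows])
    schedule = TitrationSchedule(
        v0_ul=float(meta["v0_ul"]),
        injection_volumes_ul=dv,
        syringe_um=float(meta["syringe_um"]),
        cell_um=float(meta["cell_um"]),
        temperature_c=float(meta.get("temperature_c", 25.0)),
    )
    return Thermogram(
        heats, schedule, meta["sign"] == "exothermic_positive"
    )


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Either ``simulate`` is true (synthetic inputs are generated from the
    seed) or the free/bound uptake CSV paths must exist.
    """

    output_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    fasta_path: str | None = None
    free_csv: str | None = None
    bound_csv: str | None = None
    structure_path: str | None = None
    states: tuple[str, str] = ("free", "bound")
    timepoints: tuple[float, ...] = (30.0, 300.0, 3000.0)
    n_replicates: int = 3
    noise_sd: float = 0.13
    protein_length: int = 470
    alpha_global: float = 0.05
    alpha_ttest: float = 0.05
    threshold_override: float | None = None
    threshold_df: str = "pooled"
    consensus_rule: str = "any"
    consensus_timepoint: float = 3000.0
    classification: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.simulate:
            for label, p in (("free_csv", self.free_csv),
                             ("bound_csv", self.bound_csv)):
                if p is None:
                    raise ValueError(f"{label} required when simulate=false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: {p} does not exist")
            if self.fasta_path is not None and not Path(self.fasta_path).exists():
                raise FileNotFoundError(f"fasta_path: {self.fasta_path}")
        if self.consensus_rule not in ("any", "majority", "all"):
            raise ValueError(f"bad consensus rule {self.consensus_rule!r}")
        if self.consensus_timepoint not in self.timepoints:
            raise ValueError("consensus_timepoint must be one of timepoints")
        for alpha in (self.alpha_global, self.alpha_ttest):
            if not (0 < alpha < 1):
                raise ValueError("alphas must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["states"] = list(self.states)
        d["timepoints"] = list(self.timepoints)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "states" in data:
            data["states"] = tuple(data["states"])
        if "timepoints" in data:
            data["timepoints"] = tuple(float(t) for t in data["timepoints"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
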