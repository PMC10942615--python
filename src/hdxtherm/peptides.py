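"""Protein constructs, peptide maps, and sequence-coverage statistics.

Bottom-up HDX-MS reads out deuterium uptake on proteolytic peptides.  This
module represents the analyzed construct (including any affinity tag), the
list of confirmed peptides with their residue ranges, and the coverage /
redundancy statistics that describe how well the peptide pool tiles the
sequence.

Coordinates are 1-based inclusive on the construct as stored.  Reported
(display) positions add ``numbering_offset`` — e.g. an offset of -1 when the
initiator methionine is processed off the mature protein.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein construct with 1-based internal numbering.

    Parameters
    ----------
    id : str
        Identifier (FASTA record id).
    sequence : str
        One-letter amino-acid codes, 20-letter alphabet.
    numbering_offset : int, default 0
        Reported position = internal position + offset.
    """

    id: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("protein sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def display_position(self, position: int) -> int:
        return position + self.numbering_offset


@dataclass(frozen=True)
class Peptide:
    """A confirmed peptide on the construct, 1-based inclusive range.

    ``n_max`` is the theoretic maximum number of exchange-observable amide
    deuterons: the first residue's amide back-exchanges too fast to observe
    and prolines carry no amide hydrogen, so
    ``n_max = length - 1 - (# prolines at positions 2..length)``.
    """

    start: int
    end: int
    sequence: str
    n_max: int = field(default=-1)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad peptide range ({self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match range "
                f"({self.start}, {self.end})"
            )
        if self.n_max < 0:
            object.__setattr__(
                self, "n_max", count_exchangeable_amides(self.sequence)
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def amide_positions(self) -> list[int]:
        """Construct positions carrying an observable amide (start+1..end,
        prolines excluded)."""
        return [
            self.start + i
            for i in range(1, self.length)
            if self.sequence[i] != "P"
        ]


def count_exchangeable_amides(peptide_sequence: str) -> int:
    """Number of exchange-observable amide hydrogens of a peptide.

    The N-terminal residue is excluded (fast back-exchange of the first
    amide) and prolines at positions 2..L contribute no amide.
    """
    if not peptide_sequence:
        raise ValueError("empty peptide sequence")
    bad = set(peptide_sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue codes: {sorted(bad)}")
    return len(peptide_sequence) - 1 - peptide_sequence[1:].count("P")


@dataclass(frozen=True)
class PeptideMap:
    protein: ProteinSequence
    peptides: tuple[Peptide, ...]

    def __post_init__(self) -> None:
        seen = set()
        for pep in self.peptides:
            if pep.end > len(self.protein):
                raise ValueError(
                    f"peptide ({pep.start}, {pep.end}) exceeds protein "
                    f"length {len(self.protein)}"
                )
            expected = self.protein.sequence[pep.start - 1 : pep.end]
            if pep.sequence != expected:
                raise ValueError(
                    f"peptide sequence {pep.sequence!r} does not match "
                    f"construct subsequence {expected!r} at "
                    f"({pep.start}, {pep.end})"
                )
            key = (pep.start, pep.end)
            if key in seen:
                raise ValueError(f"duplicate peptide range {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peptides)

    def covered_positions(self) -> set[int]:
        covered: set[int] = set()
        for pep in self.peptides:
            covered.update(range(pep.start, pep.end + 1))
        return covered


@dataclass(frozen=True)
class CoverageStats:
    coverage_percent: float
    n_peptides: int
    mean_peptide_length: float
    redundancy: float
    n_uncovered_residues: int
    covered_positions: frozenset[int]


def build_peptide_map(
    protein: ProteinSequence, ranges: Iterable[tuple[int, int]]
) -> PeptideMap:
    """Build a deduplicated peptide map, sorted by (start, end).

    Sequences and n_max are filled in from the construct; out-of-bounds
    ranges are rejected with the offending range reported.
    """
    unique = sorted(set((int(s), int(e)) for s, e in ranges))
    peptides = []
    for start, end in unique:
        if not (1 <= start <= end <= len(protein)):
            raise ValueError(
                f"range ({start}, {end}) out of bounds for protein of "
                f"length {len(protein)}"
            )
        peptides.append(
            Peptide(start, end, protein.sequence[start - 1 : end])
        )
    return PeptideMap(protein, tuple(peptides))


def coverage_stats(pmap: PeptideMap) -> CoverageStats:
    """Sequence coverage, mean peptide length and redundancy of a map.

    Coverage counts every residue of a covered range (first residues and
    prolines included); redundancy is the summed peptide length divided by
    the number of covered residues.
    """
    length = len(pmap.protein)
    covered = pmap.covered_positions()
    n_cov = len(covered)
    n_pep = len(pmap.peptides)
    total_len = sum(p.length for p in pmap.peptides)
    return CoverageStats(
        coverage_percent=100.0 * n_cov / length,
        n_peptides=n_pep,
        mean_peptide_length=(total_len / n_pep) if n_pep else 0.0,
        redundancy=(total_len / n_cov) if n_cov else 0.0,
        n_uncovered_residues=length - n_cov,
        covered_positions=frozenset(covered),
    )


def read_fasta(path) -> ProteinSequence:
    """Read a single-record FASTA into a ProteinSequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {path}, got {len(records)}"
        )
    rec = records[0]
    return ProteinSequence(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(protein: ProteinSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{protein.id}\n")
        seq = protein.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


POOL_HEADER = ["protein_id", "start", "end", "sequence"]


def read_peptide_pool_csv(path, protein: ProteinSequence) -> PeptideMap:
    """Read a peptide pool CSV (``protein_id,start,end,sequence``)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != POOL_HEADER:
            raise ValueError(
                f"bad peptide pool header {reader.fieldnames}, "
                f"expected {POOL_HEADER}"
            )
        ranges = []
        for lineno, row in enumerate(reader, start=2):
            try:
                start, end = int(row["start"]), int(row["end"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row") from exc
            expected = protein.sequence[start - 1 : end]
            if row["sequence"] and row["sequence"] != expected:
                raise ValueError(
                    f"{path}:{lineno}: sequence {row['sequence']!r} does not "
                    f"match construct at ({start}, {end})"
                )
            ranges.append((start, end))
    return build_peptide_map(protein, ranges)


def write_peptide_pool_csv(pmap: PeptideMap, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(POOL_HEADER)
        for pep in pmap.peptides:
            writer.writerow([pmap.protein.id, pep.start, pep.end, pep.sequence])
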