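"""Peptide-to-residue consensus mapping and structure annotation."""

import numpy as np
import pandas as pd
import pytest

import hdxtherm as ht
from hdxtherm import consensus

# A tiny synthetic three-residue structure (poly-ALA backbone), generated by
# hand for annotation round-trips; not derived from any deposited model.
SYNTHETIC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.100   2.700   0.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.500   2.300   0.000  1.00  0.00           C
ATOM      7  N   ALA A   3       6.400   3.300   0.000  1.00  0.00           N
ATOM      8  CA  ALA A   3       7.800   3.000   0.000  1.00  0.00           C
ATOM      9  C   ALA A   3       8.600   4.300   0.000  1.00  0.00           C
END
"""


def _deltas(records):
    """records: (start, end, timepoint, delta, significant, direction)."""
    return pd.DataFrame(
        records,
        columns=["start", "end", "timepoint_s", "delta", "significant",
                 "direction"],
    )


@pytest.fixture()
def ten_residue_map():
    protein = ht.ProteinSequence("p", "ACDEFGHIKL")
    return ht.build_peptide_map(protein, [(1, 5), (4, 9)])


class TestMapSignificance:
    def test_any_rule_worked_example(self, ten_residue_map):
        deltas = _deltas([
            (1, 5, 3000.0, -0.5, True, "protected"),
            (4, 9, 3000.0, -0.1, False, "none"),
        ])
        status = consensus.map_significance_to_residues(
            deltas, ten_residue_map, 3000.0, rule="any"
        )
        by_pos = status.set_index("position")["status"]
        assert list(by_pos.loc[2:5]) == ["protected"] * 4
        assert list(by_pos.loc[6:9]) == ["insignificant"] * 4
        assert by_pos.loc[1] == "uncovered"
        assert by_pos.loc[10] == "uncovered"

    def test_no_significant_peptides(self, ten_residue_map):
        deltas = _deltas([
            (1, 5, 3000.0, -0.1, False, "none"),
            (4, 9, 3000.0, 0.1, False, "none"),
        ])
        status = consensus.map_significance_to_residues(
            deltas, ten_residue_map, 3000.0
        )
        assert not status["status"].isin(["protected", "deprotected"]).any()

    def test_all_rule_requires_every_contributor(self, ten_residue_map):
        deltas = _deltas([
            (1, 5, 3000.0, -0.5, True, "protected"),
            (4, 9, 3000.0, -0.1, False, "none"),
        ])
        status = consensus.map_significance_to_residues(
            deltas, ten_residue_map, 3000.0, rule="all"
        )
        by_pos = status.set_index("position")["status"]
        # positions 5 is shared by both peptides: only one significant
        assert by_pos.loc[5] == "insignificant"
        # positions 2-4 are observed by peptide (1,5) only... position 4 is
        # also the start of (4,9), whose amides begin at 5
        assert list(by_pos.loc[2:4]) == ["protected"] * 3

    def test_direction_conflict_resolves_to_protected(self, ten_residue_map, caplog):
        deltas = _deltas([
            (1, 5, 3000.0, -0.5, True, "protected"),
            (4, 9, 3000.0, 0.5, True, "deprotected"),
        ])
        with caplog.at_level("WARNING"):
            status = consensus.map_significance_to_residues(
                deltas, ten_residue_map, 3000.0
            )
        assert status.set_index("position").loc[5, "status"] == "protected"
        assert "conflict" in caplog.text

    def test_unknown_timepoint_rejected(self, ten_residue_map):
        deltas = _deltas([(1, 5, 30.0, -0.5, True, "protected")])
        with pytest.raises(ValueError):
            consensus.map_significance_to_residues(
                deltas, ten_residue_map, 3000.0
            )

    @pytest.mark.parametrize("rule", ["any", "majority", "all"])
    def test_matches_brute_force_on_random_instances(self, rule):
        rng = np.random.default_rng(11)
        protein = ht.ProteinSequence(
            "p", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
        )
        for _ in range(12):
            n_pep = rng.integers(1, 8)
            ranges = set()
            for _ in range(n_pep):
                s = int(rng.integers(1, 28))
                e = int(rng.integers(s, min(30, s + 12)))
                ranges.add((s, e))
            pmap = ht.build_peptide_map(protein, ranges)
            recs = []
            for p in pmap.peptides:
                sig = bool(rng.random() < 0.4)
                direction = (
                    rng.choice(["protected", "deprotected"]) if sig else "none"
                )
                recs.append(
                    (p.start, p.end, 3000.0, rng.normal(), sig, direction)
                )
            deltas = _deltas(recs)
            got = consensus.map_significance_to_residues(
                deltas, pmap, 3000.0, rule
            )["status"].tolist()
            ref = consensus.brute_force_residue_status(
                deltas, pmap, 3000.0, rule
            )
            assert got == ref

    def test_adding_significant_peptide_is_monotone_under_any(
        self, ten_residue_map
    ):
        base = _deltas([(1, 5, 3000.0, -0.1, False, "none")])
        more = _deltas([
            (1, 5, 3000.0, -0.1, False, "none"),
            (4, 9, 3000.0, -0.6, True, "protected"),
        ])
        s_base = consensus.map_significance_to_residues(
            base, ten_residue_map, 3000.0
        )
        s_more = consensus.map_significance_to_residues(
            more, ten_residue_map, 3000.0
        )
        rank = {"uncovered": 0, "insignificant": 0, "protected": 1,
                "deprotected": 1}
        assert all(
            rank[a] <= rank[b]
            for a, b in zip(s_base["status"], s_more["status"])
        )


class TestPositionCounts:
    def test_counts_conserve_protein_length(self, study_run):
        status = consensus.map_significance_to_residues(
            study_run["deltas"], study_run["pmap"], 3000.0
        )
        counts = consensus.position_counts(status)
        assert sum(counts.values()) == len(study_run["pmap"].protein)

    def test_all_uncovered(self, small_protein):
        pmap = ht.build_peptide_map(small_protein, [])
        status = consensus.map_significance_to_residues(
            _deltas([(1, 2, 30.0, 0, False, "none")]), pmap, 30.0
        )
        counts = consensus.position_counts(status)
        assert counts["uncovered"] == len(small_protein)

    def test_footprint_recovery_count_near_truth(self, study_run):
        """Protected-position count lands near the ground-truth footprint
        amide count on the default simulation."""
        status = consensus.map_significance_to_residues(
            study_run["deltas"], study_run["pmap"], 3000.0
        )
        truth = study_run["truth"]
        counts = consensus.position_counts(status)
        target = len(truth.footprint_protected)
        assert abs(counts["protected"] - target) <= 0.2 * target


class TestStructureAnnotation:
    def _statusmap(self, statuses, deltas):
        return pd.DataFrame(
            {
                "position": range(1, len(statuses) + 1),
                "display_position": range(1, len(statuses) + 1),
                "status": statuses,
                "n_peptides": [1] * len(statuses),
                "mean_delta_da": deltas,
            }
        )

    def test_round_trip_values(self, tmp_path):
        import gemmi

        pdb = tmp_path / "toy.pdb"
        pdb.write_text(SYNTHETIC_PDB)
        smap = self._statusmap(
            ["insignificant", "protected", "uncovered"], [0.0, -0.5, np.nan]
        )
        out = tmp_path / "annotated.pdb"
        matched = consensus.write_structure_annotation(smap, pdb, out)
        assert matched == 3
        structure = gemmi.read_structure(str(out))
        b = [res[0].b_iso for res in structure[0]["A"]]
        assert b[0] == pytest.approx(0.0)
        assert b[1] == pytest.approx(-0.5)
        assert b[2] == pytest.approx(-99.0)

    def test_status_codes_written(self, tmp_path):
        import gemmi

        pdb = tmp_path / "toy.pdb"
        pdb.write_text(SYNTHETIC_PDB)
        smap = self._statusmap(
            ["protected", "deprotected", "insignificant"], [-0.5, 0.4, 0.0]
        )
        out = tmp_path / "annotated.pdb"
        consensus.write_structure_annotation(smap, pdb, out, value="status")
        structure = gemmi.read_structure(str(out))
        b = [res[0].b_iso for res in structure[0]["A"]]
        assert b == [pytest.approx(-1.0), pytest.approx(1.0),
                     pytest.approx(0.0)]

    def test_no_match_rejected(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(SYNTHETIC_PDB)
        smap = self._statusmap(["insignificant"], [0.0])
        with pytest.raises(ValueError, match="no residue"):
            consensus.write_structure_annotation(
                smap, pdb, tmp_path / "out.pdb", structure_offset=500
            )
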