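"""PDB parsing, Kabsch superposition and pocket-access distances.

The Kabsch rotation is cross-checked against scipy's align_vectors and
against a Monte-Carlo bound (no random rigid transform may beat the
least-squares fit).
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wee1kit import synthetic
from wee1kit.pairwise import global_align
from wee1kit.seqio import SequenceRecord
from wee1kit.structure import (
    StructureError,
    gate_access_report,
    gate_table_tsv,
    kabsch_superpose,
    pair_residues,
    parse_selector,
    read_pdb,
    residue_distance,
    superpose_structures,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLU A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BGLU A   1       9.000   0.000   0.000  0.40  0.00           C
END
"""


class TestReadPdb:
    def test_minimal_fixture(self):
        st = read_pdb(MINIMAL_PDB)
        assert len(st.atoms) == 2
        assert st.atoms[1].x == pytest.approx(3.8)
        assert st.sequence("A") == "GA"

    def test_altloc_highest_occupancy_kept(self):
        st = read_pdb(ALTLOC_PDB)
        assert len(st.atoms) == 1
        assert st.atoms[0].x == pytest.approx(0.0)  # the 0.60 copy

    def test_hetatm_ignored_by_default(self):
        text = MINIMAL_PDB.replace("END", "") + \
            "HETATM    3  O   HOH A 100      1.000   1.000   1.000  1.00  0.00           O\nEND\n"
        assert len(read_pdb(text).atoms) == 2
        assert len(read_pdb(text, keep_hetatm=True).atoms) == 3

    def test_unparseable_atom_line_reports_lineno(self):
        bad = MINIMAL_PDB.replace("3.800", "3.8zz")
        with pytest.raises(StructureError, match="line 2"):
            read_pdb(bad)

    def test_write_read_round_trip(self, tmp_path):
        gate = synthetic.simulate_gate(8.3, seed=3)
        p = tmp_path / "gate.pdb"
        write_pdb(gate, p)
        back = read_pdb(p)
        assert len(back.atoms) == len(gate.atoms)
        for a, b in zip(gate.atoms, back.atoms):
            assert (a.name, a.resname, a.chain, a.resnum) == \
                (b.name, b.resname, b.chain, b.resnum)
            assert np.allclose(a.xyz, b.xyz, atol=1e-3)  # PDB writes 3 decimals


class TestKabsch:
    def test_identity(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch_superpose(A, A)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.translation, 0, atol=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_transform(self, rng):
        A = rng.normal(size=(50, 3))
        R = Rotation.random(random_state=7).as_matrix()
        t = np.array([4.0, -2.0, 9.0])
        B = A @ R.T + t
        res = kabsch_superpose(A, B)
        assert np.allclose(res.rotation, R, atol=1e-9)
        assert np.allclose(res.translation, t, atol=1e-9)
        assert res.rmsd < 1e-9

    def test_matches_scipy_with_noise(self, rng):
        A = rng.normal(size=(80, 3))
        R = Rotation.random(random_state=11).as_matrix()
        B = A @ R.T + rng.normal(0, 0.4, size=A.shape) + [1, 2, 3]
        res = kabsch_superpose(A, B)
        rot, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert np.allclose(res.rotation, rot.as_matrix(), atol=1e-9)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(A)), rel=1e-6)

    def test_beats_random_rigid_transforms(self, rng):
        """Monte-Carlo oracle: no random proper rigid motion does better."""
        A = rng.normal(size=(40, 3))
        R = Rotation.random(random_state=5).as_matrix()
        B = A @ R.T + rng.normal(0, 0.8, size=A.shape)
        best = kabsch_superpose(A, B).rmsd
        for trial_rot in Rotation.random(1000, random_state=99):
            Rr = trial_rot.as_matrix()
            # optimal translation for any fixed rotation matches centroids
            tr = B.mean(0) - Rr @ A.mean(0)
            rmsd = np.sqrt((((A @ Rr.T + tr) - B) ** 2).sum(1).mean())
            assert best <= rmsd + 1e-12

    def test_rotation_proper_even_under_reflection_pressure(self, rng):
        for _ in range(20):
            A = rng.normal(size=(4, 3))
            B = rng.normal(size=(4, 3))  # unrelated: worst case for SVD sign
            res = kabsch_superpose(A, B)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3),
                               atol=1e-9)

    def test_rmsd_invariant_under_common_motion(self, rng):
        A = rng.normal(size=(30, 3))
        B = A + rng.normal(0, 0.3, size=A.shape)
        base = kabsch_superpose(A, B).rmsd
        Q = Rotation.random(random_state=2).as_matrix()
        shift = np.array([5.0, 6.0, 7.0])
        moved = kabsch_superpose(A @ Q.T + shift, B @ Q.T + shift).rmsd
        assert moved == pytest.approx(base, rel=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(StructureError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(StructureError, match="collinear"):
            kabsch_superpose(A, A.copy())


class TestPairResidues:
    def _structs(self):
        a, b, _ = synthetic.simulate_structure_pair(
            20, (np.array([0.0, 0, 1]), 30.0), [1, 1, 1], 0.0, seed=8)
        return a, b

    def test_identity_alignment_pairs_everything(self, scheme):
        a, b = self._structs()
        seq = a.sequence("A")
        aln = global_align(SequenceRecord(id="a", residues=seq),
                          SequenceRecord(id="b", residues=seq), scheme)
        pairs = pair_residues(a, b, aln)
        assert len(pairs) == 20

    def test_superpose_structures_recovers_truth(self, scheme):
        a, b, truth = synthetic.simulate_structure_pair(
            30, (np.array([1.0, 1, 0]), 55.0), [2, 0, -1], 0.0, seed=12)
        seq = a.sequence("A")
        aln = global_align(SequenceRecord(id="a", residues=seq),
                          SequenceRecord(id="b", residues=seq), scheme)
        res = superpose_structures(a, b, aln)
        assert np.allclose(res.rotation, truth["rotation"], atol=1e-6)
        assert res.rmsd < 1e-6

    def test_missing_ca_drops_pair(self, scheme):
        a, b = self._structs()
        # remove one CA from b
        from wee1kit.structure import Structure
        b2 = Structure(name=b.name, atoms=tuple(
            at for at in b.atoms if not (at.resnum == 5 and at.name == "CA")))
        seq_a = a.sequence("A")
        seq_b = b2.sequence("A")
        aln = global_align(SequenceRecord(id="a", residues=seq_a),
                          SequenceRecord(id="b", residues=seq_b), scheme)
        pairs = pair_residues(a, b2, aln)
        assert len(pairs) == 19

    def test_sequence_mismatch_rejected(self, scheme):
        a, b = self._structs()
        wrong = "W" * 20
        aln = global_align(SequenceRecord(id="a", residues=wrong),
                          SequenceRecord(id="b", residues=wrong), scheme)
        with pytest.raises(StructureError, match="mismatch"):
            pair_residues(a, b, aln)


class TestResidueDistance:
    def test_three_four_five_triangle(self):
        pdb = (
            "ATOM      1  SG  CYS A   1       0.000   0.000   0.000  1.00  0.00           S\n"
            "ATOM      2  SG  CYS A   2       3.000   4.000   0.000  1.00  0.00           S\n"
            "END\n")
        st = read_pdb(pdb)
        m = residue_distance(st, "A:1", "A:2")
        assert m.distance == pytest.approx(5.0)

    def test_same_residue_zero(self):
        st = read_pdb(MINIMAL_PDB)
        m = residue_distance(st, "A:1", "A:1", mode="min-heavy")
        assert m.distance == 0.0

    def test_symmetric_in_arguments(self):
        gate = synthetic.simulate_gate(11.3, seed=6)
        d1 = residue_distance(gate, "A:309", "A:518")
        d2 = residue_distance(gate, "A:518", "A:309")
        assert d1.distance == pytest.approx(d2.distance)

    def test_backbone_excluded_in_side_chain_mode(self):
        gate = synthetic.simulate_gate(8.3, seed=1)
        m = residue_distance(gate, "A:309", "A:518")
        assert m.atom_a not in {"N", "CA", "C", "O"}
        assert m.atom_b not in {"N", "CA", "C", "O"}

    def test_glycine_falls_back_to_ca(self):
        st = read_pdb(MINIMAL_PDB)  # GLY with only CA
        m = residue_distance(st, "A:1", "A:1")
        assert m.atom_a == "CA"

    def test_unknown_selector(self):
        st = read_pdb(MINIMAL_PDB)
        with pytest.raises(StructureError, match="no residue"):
            residue_distance(st, "A:99", "A:1")

    def test_selector_parsing(self):
        assert parse_selector("A:309") == ("A", 309, "")
        assert parse_selector("B:52A") == ("B", 52, "A")
        with pytest.raises(StructureError):
            parse_selector("309")


class TestGateAccessReport:
    def test_planted_distances_reported(self):
        structs = [("human", synthetic.simulate_gate(8.0, seed=1)),
                   ("plant", synthetic.simulate_gate(14.0, seed=2))]
        rows = gate_access_report(structs, ("A:309", "A:518"))
        assert [r.structure for r in rows] == ["human", "plant"]
        assert rows[0].distance == pytest.approx(8.0, abs=1e-6)
        assert rows[1].distance == pytest.approx(14.0, abs=1e-6)

    def test_single_structure(self):
        rows = gate_access_report(
            [("only", synthetic.simulate_gate(5.0, seed=4))],
            ("A:309", "A:518"))
        assert len(rows) == 1

    def test_empty_list(self):
        assert gate_access_report([], ("A:309", "A:518")) == []

    def test_tsv_has_mode_and_atoms(self):
        rows = gate_access_report(
            [("s", synthetic.simulate_gate(8.3, seed=1))], ("A:309", "A:518"))
        tsv = gate_table_tsv(rows)
        assert "min-side-chain-heavy" in tsv
        assert "8.300" in tsv
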