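"""Consensus scanning, physicochemical classes, site calls and flags."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from wee1kit import synthetic
from wee1kit.motif import (
    CATALYTIC_CONSENSUS,
    HYDROPHOBIC,
    MotifError,
    ReferenceSiteCatalog,
    assess_function,
    builtin_wee1_catalog,
    call_sites,
    classify_residue,
    locate_functional_motifs,
    scan_consensus,
)
from wee1kit.msa import MultipleAlignment, progressive_align
from wee1kit.refanchor import build_column_map, pairwise_column_map
from wee1kit.seqio import AMINO_ACIDS, AlignedRecord, SequenceRecord


def naive_scan(text, pattern, relaxed=False):
    hits = []
    for start in range(len(text) - len(pattern) + 1):
        ok = True
        for p, aa in zip(pattern, text[start:]):
            if p == "x" or p == aa:
                continue
            if relaxed and p in HYDROPHOBIC and aa in HYDROPHOBIC:
                continue
            ok = False
            break
        if ok:
            hits.append((start + 1, text[start:start + len(pattern)]))
    return hits


class TestScanConsensus:
    def test_simple_motif(self):
        assert scan_consensus("AAEGDAA", "EGD") == [(3, "EGD")]

    def test_wildcard(self):
        assert scan_consensus("MDLKPENQ", "DLKPxN") == [(2, "DLKPEN")]

    def test_missing_catalytic_d_no_match(self):
        seq = "AAIVHRALKPENILAA"  # D of the consensus replaced by A
        assert scan_consensus(seq, CATALYTIC_CONSENSUS) == []

    def test_relaxed_hydrophobic(self):
        # L in the pattern accepts V only in relaxed mode
        assert scan_consensus("AVA", "ALA") == []
        assert scan_consensus("AVA", "ALA", relaxed_hydrophobic=True) == \
            [(1, "AVA")]

    def test_invalid_pattern_character(self):
        with pytest.raises(MotifError):
            scan_consensus("MKV", "M?V")

    @settings(max_examples=80, deadline=None)
    @given(
        st.text(alphabet="ACDEGILV", min_size=1, max_size=200),
        st.text(alphabet="ACDEGILVx", min_size=1, max_size=5),
        st.booleans(),
    )
    def test_equals_sliding_window_oracle(self, text, pattern, relaxed):
        assert scan_consensus(text, pattern, relaxed_hydrophobic=relaxed) == \
            naive_scan(text, pattern, relaxed)


class TestClassifyResidue:
    @pytest.mark.parametrize("aa,cls", [
        ("E", "acidic"), ("D", "acidic"), ("W", "hydrophobic"),
        ("R", "basic"), ("Q", "polar"), ("H", "aromatic"), ("Y", "aromatic"),
        ("C", "cysteine"), ("P", "proline"), ("G", "glycine"),
        ("X", "unknown"),
    ])
    def test_examples(self, aa, cls):
        assert classify_residue(aa) == cls

    def test_all_residues_covered_disjointly(self):
        seen = {}
        for aa in AMINO_ACIDS:
            cls = classify_residue(aa)
            seen.setdefault(cls, []).append(aa)
        assert sum(len(v) for v in seen.values()) == 20
        assert set("".join("".join(v) for v in seen.values())) == set(AMINO_ACIDS)

    def test_invalid_letter(self):
        with pytest.raises(MotifError):
            classify_residue("B")


class TestBuiltinCatalog:
    def test_core_sites_present(self, catalog):
        cat_d = catalog.site("catalytic-D")
        assert cat_d.ref_start == 426 and cat_d.expected == (frozenset("D"),)
        gk = catalog.site("gatekeeper")
        assert gk.ref_start == 376 and gk.expected == (frozenset("N"),)
        dfg = catalog.site("DFG")
        assert dfg.ref_start == 463
        assert dfg.expected[1] == frozenset("LF")  # human L, plant F: both fine
        egd = catalog.site("EGD")
        assert egd.ref_start == 477
        assert catalog.site("R518").ref_start == 518

    def test_site_positions_unique_per_name(self, catalog):
        names = [s.name for s in catalog.sites]
        assert len(set(names)) == len(names)

    def test_consensus_anchor(self, catalog):
        (pat,) = catalog.consensus_patterns
        assert pat.pattern == "IVHxDLKPxNIx"
        assert pat.anchor_start == 422

    def test_json_round_trip(self, catalog, tmp_path):
        path = tmp_path / "catalog.json"
        catalog.save(path)
        back = ReferenceSiteCatalog.load(path)
        assert back == catalog


class TestCallSitesAndFlags:
    def _anchored(self, ref, query):
        return pairwise_column_map(ref, query)

    def test_reference_all_conserved(self, wee1_reference, catalog):
        msa = MultipleAlignment(records=(
            AlignedRecord(id=wee1_reference.id,
                          residues=wee1_reference.residues),))
        cmap = build_column_map(msa, wee1_reference.id)
        table = call_sites(msa, cmap, catalog)
        assert all(c.status == "conserved" for c in table.calls.values())
        flags = assess_function(table)
        assert flags[0].flags == frozenset()

    def test_planted_substitution_called_exactly(self, wee1_reference, catalog,
                                                 site_positions):
        spec = synthetic.FamilySpec(
            reference=wee1_reference, n_taxa=4, seed=5, subst_prob=0.02,
            planted=(synthetic.PlantedEvent("t02", 426, "A"),),
            protected_positions=site_positions)
        records, _ = synthetic.simulate_family(spec)
        msa = progressive_align(records)
        cmap = build_column_map(msa, wee1_reference.id)
        table = call_sites(msa, cmap, catalog)
        non_conserved = {(c.seq_id, c.site) for c in table.non_conserved()}
        assert non_conserved == {("t02", "catalytic-D")}

    def test_planted_recovery_recall_precision_one(self, wee1_reference,
                                                   catalog, site_positions):
        planted = (
            synthetic.PlantedEvent("t01", 426, "A"),
            synthetic.PlantedEvent("t03", 463, "G"),
            synthetic.PlantedEvent("t04", 518, "E"),
        )
        spec = synthetic.FamilySpec(
            reference=wee1_reference, n_taxa=5, seed=9, subst_prob=0.03,
            planted=planted, protected_positions=site_positions)
        records, truth = synthetic.simulate_family(spec)
        msa = progressive_align(records)
        cmap = build_column_map(msa, wee1_reference.id)
        table = call_sites(msa, cmap, catalog)
        found = {(c.seq_id, c.site) for c in table.non_conserved()}
        site_of = {426: "catalytic-D", 463: "DFG", 518: "R518"}
        expected = {(e.taxon, site_of[e.ref_pos]) for e in truth.planted}
        assert found == expected  # recall = precision = 1

    def test_conservative_vs_class_change(self, wee1_reference, catalog):
        # E309 -> D keeps the acidic class; E309 -> H changes class
        for new, status in (("D", "conservative"), ("H", "class-change")):
            seq = list(wee1_reference.residues)
            seq[308] = new
            q = SequenceRecord(id="q", residues="".join(seq))
            msa, cmap = self._anchored(wee1_reference, q)
            table = call_sites(msa, cmap, catalog)
            assert table.call("q", "G-loop-E309").status == status

    def test_degenerate_duplicate_flagged_dead(self, study_family, catalog):
        """The legume duplicate surrogate lacking both aspartates is flagged
        catalytic-dead and ATP-binding-compromised."""
        ref, plants = study_family
        chr61 = next(p for p in plants if p.id == "VuChr61_syn")
        msa, cmap = self._anchored(ref, chr61)
        table = call_sites(msa, cmap, catalog)
        assert table.call(chr61.id, "catalytic-D").status != "conserved"
        flags = {f.seq_id: f.flags for f in assess_function(table)}
        assert {"catalytic-dead", "ATP-binding-compromised"} <= flags[chr61.id]
        assert flags[ref.id] == frozenset()

    def test_dfg_l_to_f_never_flags(self, wee1_reference, catalog):
        # plant DFG vs human DLG: the L/F exchange is within expectation
        seq = list(wee1_reference.residues)
        assert seq[463] == "L"
        seq[463] = "F"
        q = SequenceRecord(id="q", residues="".join(seq))
        msa, cmap = self._anchored(wee1_reference, q)
        table = call_sites(msa, cmap, catalog)
        assert table.call("q", "DFG").status == "conserved"
        flags = {f.seq_id: f.flags for f in assess_function(table)}
        assert "ATP-binding-compromised" not in flags["q"]

    def test_missing_site_after_truncation(self, wee1_reference, catalog):
        # a query cut before position 518 shows a missing R518 site
        q = SequenceRecord(id="q", residues=wee1_reference.residues[:500])
        msa, cmap = pairwise_column_map(wee1_reference, q)
        table = call_sites(msa, cmap, catalog)
        assert table.call("q", "R518").status == "missing"

    def test_tsv_export_shape(self, wee1_reference, catalog):
        msa, cmap = pairwise_column_map(
            wee1_reference,
            SequenceRecord(id="q", residues=wee1_reference.residues[30:]))
        table = call_sites(msa, cmap, catalog)
        lines = table.to_tsv().strip().splitlines()
        assert len(lines) == 3  # header + 2 sequences
        assert lines[0].split("\t")[1:] == list(table.site_names)


class TestLocateFunctionalMotifs:
    def test_reference_layout_recovered(self, wee1_reference):
        mp = locate_functional_motifs(wee1_reference)
        assert mp.catalytic_asp == 426
        assert mp.dfg_asp == 463
        assert mp.egd_start == 477

    def test_plant_surrogates_shifted_by_truncation(self, study_family):
        ref, plants = study_family
        at = next(p for p in plants if p.id == "AtWEE1_syn")
        mp = locate_functional_motifs(at)
        assert mp.catalytic_asp == 426 - 50
        assert mp.egd_start == 477 - 50

    def test_absent_consensus_raises(self):
        with pytest.raises(MotifError, match="consensus"):
            locate_functional_motifs(
                SequenceRecord(id="q", residues="MKVLW" * 20))
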