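"""Isomery rules R1-R4, topology hints, rendering, catalog, D statistics."""

import pytest

from nrpsmith import (
    CatalogEntry,
    DomainToken as D,
    DStatistics,
    IsomeryState as I,
    Organism,
    Topology,
    concat_assembly,
    d_statistics,
    infer_isomery,
    match_catalog,
    parse_architecture,
    parse_monomer_string,
    predict_structure,
    predict_topology,
    prediction_to_monomer_string,
    render_monomer_string,
    render_norine,
)
from nrpsmith.data import (
    BACITRACIN_ARCHITECTURES,
    DC3000_ARCHITECTURES,
    PYOVERDIN_CHROMOPHORES,
    PYOVERDIN_MONOMERS,
    PYOVERDIN_SIDE_CHAIN,
    SYRINGAFACTIN,
)
from nrpsmith.isomery import IsomeryError


def _assembly(*pids, organism=Organism.UNKNOWN, table=DC3000_ARCHITECTURES):
    return concat_assembly(
        [(p, parse_architecture(table[p])) for p in pids], organism
    )


def _d_positions(calls):
    return [c.position for c in calls if c.isomery is I.D]


class TestInferIsomery:
    def test_bacitracin_four_d_from_e_modules(self):
        asm = concat_assembly(
            [(p, parse_architecture(a)) for p, a in BACITRACIN_ARCHITECTURES]
        )
        assert asm.n_modules == 12
        assert [m.index for m in asm.modules if m.has_E] == [4, 7, 9, 11]
        calls = infer_isomery(asm)
        assert _d_positions(calls) == [4, 7, 9, 11]
        assert all(
            c.isomery is I.L for c in calls if c.position not in (4, 7, 9, 11)
        )

    def test_syringafactin_dual_ce_epimerizes_preceding_position(self):
        asm = _assembly(*SYRINGAFACTIN, organism=Organism.PSEUDOMONAS)
        ce = [m.index for m in asm.modules if m.leading_c is D.CE]
        assert ce == [2, 3, 4, 6, 8]
        assert _d_positions(infer_isomery(asm)) == [1, 2, 3, 5, 7]

    def test_all_lcl_assembly_has_no_d(self):
        asm = concat_assembly(
            [("p", parse_architecture("LCL-A-T-LCL-A-T-LCL-A-T-Te"))]
        )
        assert _d_positions(infer_isomery(asm)) == []

    def test_e_without_following_dcl_warns_but_keeps_d(self):
        asm = concat_assembly(
            [("p", parse_architecture("LCL-A-T-E-LCL-A-T"))]
        )
        calls = infer_isomery(asm)
        assert calls[0].isomery is I.D
        assert "E_WITHOUT_DCL" in calls[0].warnings

    def test_ce_on_module_one_warns_without_call(self):
        asm = concat_assembly([("p", parse_architecture("C/E-A-T-LCL-A-T"))])
        calls = infer_isomery(asm)
        assert "CE_NO_PRECEDING" in calls[0].warnings
        assert _d_positions(calls) == []

    def test_dcl_without_upstream_e_gives_unconfirmed_d(self):
        asm = concat_assembly([("p", parse_architecture("LCL-A-T-DCL-A-T"))])
        calls = infer_isomery(asm)
        assert calls[0].isomery is I.D_UNCONFIRMED
        assert "R3" in calls[0].rationale

    def test_racemase_flags_ala_positions(self):
        asm = concat_assembly([("p", parse_architecture("LCL-A-T-LCL-A-T"))])
        calls = infer_isomery(asm, [["Ala"], ["Leu"]], racemase_present=True)
        assert calls[0].isomery is I.D_UNCONFIRMED
        assert "Alanine racemase" in calls[0].rationale
        assert calls[1].isomery is I.L

    def test_d_is_absorbing_over_unconfirmed(self):
        # E in module 1 and DCL leading module 2: R1's D call survives R3
        asm = concat_assembly([("p", parse_architecture("LCL-A-T-E-DCL-A-T"))])
        calls = infer_isomery(asm)
        assert calls[0].isomery is I.D
        assert "R1" in calls[0].rationale

    def test_prediction_count_matches_module_count(self):
        with pytest.raises(IsomeryError, match="candidate lists"):
            infer_isomery(
                concat_assembly([("p", parse_architecture("LCL-A-T"))]), [["A"], ["B"]]
            )


class TestPredictTopology:
    def test_pseudomonas_clp_pattern(self):
        asm = _assembly(*SYRINGAFACTIN, organism=Organism.PSEUDOMONAS)
        topo, lipo, clp = predict_topology(asm)
        assert lipo and clp

    def test_single_te_is_not_clp(self):
        asm = _assembly("NP_794446", organism=Organism.PSEUDOMONAS)
        topo, lipo, clp = predict_topology(asm)
        assert lipo and not clp

    def test_e_domains_block_clp(self):
        asm = _assembly(*PYOVERDIN_SIDE_CHAIN, organism=Organism.PSEUDOMONAS)
        _, _, clp = predict_topology(asm)
        assert not clp

    def test_fungal_terminal_ct_predicts_cyclic(self):
        asm = concat_assembly(
            [("p", parse_architecture("LCL-A-T-LCL-A-T-Ct"))], Organism.FUNGUS
        )
        topo, _, _ = predict_topology(asm)
        assert topo is Topology.CYCLIC

    def test_unknown_organism_disables_genus_rules(self):
        asm = concat_assembly(
            [("p", parse_architecture("LCL-A-T-LCL-A-T-Ct"))], Organism.UNKNOWN
        )
        topo, _, clp = predict_topology(asm)
        assert topo is Topology.UNKNOWN and not clp


class TestRenderNorine:
    def test_pyoverdin_candidate_string(self):
        asm = _assembly(*PYOVERDIN_SIDE_CHAIN, organism=Organism.PSEUDOMONAS)
        pred = predict_structure(
            asm,
            PYOVERDIN_MONOMERS,
            chromophore_candidates=PYOVERDIN_CHROMOPHORES,
        )
        assert render_norine(pred) == (
            "{ChrP|ChrI|ChrD},Lys,D-{Asp|bMeAsp|OH-Asp},Thr,Thr,Ser,"
            "D-{Asp|bMeAsp|OH-Asp},Ser"
        )
        # chromophore shifts reported positions: D calls at modules 2 and 6
        # render at peptide positions 3 and 7
        d_pos = [c.position for c in pred.calls if c.isomery is I.D]
        assert d_pos == [3, 7]
        assert pred.chromophore_offset

    def test_single_monomer(self):
        asm = concat_assembly([("p", parse_architecture("A-T"))])
        pred = predict_structure(asm, [["Val"]])
        assert render_norine(pred) == "Val"

    def test_round_trip_through_monomer_string(self):
        asm = concat_assembly([("p", parse_architecture("LCL-A-T-E-DCL-A-T"))])
        pred = predict_structure(asm, [["Ser"], ["Thr"]])
        text = render_norine(pred)
        assert render_monomer_string(parse_monomer_string(text)) == text
        ms = prediction_to_monomer_string(pred)
        assert render_monomer_string(ms) == text


class TestMatchCatalog:
    def _pyoverdin_prediction(self):
        asm = _assembly(*PYOVERDIN_SIDE_CHAIN, organism=Organism.PSEUDOMONAS)
        return predict_structure(
            asm, PYOVERDIN_MONOMERS, chromophore_candidates=PYOVERDIN_CHROMOPHORES
        )

    def test_full_match_ranks_first(self):
        pred = self._pyoverdin_prediction()
        catalog = [
            CatalogEntry(
                "SYN:pyoverdin-like",  # synthetic stand-in entry
                parse_monomer_string("ChrD,Lys,D-Asp,Thr,Thr,Ser,D-Asp,Ser"),
            ),
            CatalogEntry(
                "SYN:decoy",
                parse_monomer_string("ChrD,Lys,D-Asp,Thr,Thr,Ser,D-Asp,Gly"),
            ),
        ]
        matches = match_catalog(pred, catalog, min_positional_matches=3)
        assert matches[0].entry.id == "SYN:pyoverdin-like"
        assert matches[0].full
        assert matches[1].n_matched == len(pred.calls) - 1

    def test_catalog_of_one_matching_entry(self):
        asm = concat_assembly([("p", parse_architecture("A-T"))])
        pred = predict_structure(asm, [["Val"]])
        catalog = [CatalogEntry("SYN:val", parse_monomer_string("Val"))]
        matches = match_catalog(pred, catalog)
        assert len(matches) == 1 and matches[0].full

    def test_length_mismatch_is_nonmatch_not_error(self):
        asm = concat_assembly([("p", parse_architecture("A-T"))])
        pred = predict_structure(asm, [["Val"]])
        catalog = [CatalogEntry("SYN:dipep", parse_monomer_string("Val,Leu"))]
        assert match_catalog(pred, catalog, min_positional_matches=1) == []

    def test_strict_isomery_requires_exact_state(self):
        asm = concat_assembly([("p", parse_architecture("LCL-A-T-DCL-A-T"))])
        pred = predict_structure(asm, [["Leu"], ["Ser"]])  # pos 1 D_UNCONFIRMED
        entry = CatalogEntry("SYN:d", parse_monomer_string("D-Leu,Ser"))
        assert match_catalog(pred, [entry])  # lenient: D? compatible with D
        assert not match_catalog(pred, [entry], strict_isomery=True)

    def test_empty_catalog_rejected(self):
        asm = concat_assembly([("p", parse_architecture("A-T"))])
        pred = predict_structure(asm, [["Val"]])
        with pytest.raises(IsomeryError):
            match_catalog(pred, [])


class TestDStatistics:
    def test_collection_totals_match_printed_census(self):
        # 1920 D among 11,206 monomers in 1,164 peptides: frequency 1.7e-1
        stats = DStatistics.from_counts(1164, 11206, 1920)
        assert stats.freq_D == pytest.approx(0.17134, abs=1e-4)
        assert float(f"{stats.freq_D:.1e}") == pytest.approx(1.7e-1)

    def test_gratisin_counts(self):
        ms = parse_monomer_string(
            "[Val,Orn,Leu,D-Phe,Pro,D-Tyr,Val,Orn,Leu,D-Phe,Pro,D-Tyr]"
        )
        stats = d_statistics([ms])
        assert (stats.n_monomers, stats.n_D) == (12, 4)

    def test_all_l_peptide(self):
        stats = d_statistics([parse_monomer_string("Val,Leu,Ser")])
        assert stats.n_D == 0 and stats.freq_D == 0.0
        assert stats.n_with_ge1_D == 0

    def test_counting_invariants(self):
        peptides = [
            parse_monomer_string(t)
            for t in ("Val", "D-Ala,Ser", "D-Ala,D-Phe,Gly", "Leu,Leu")
        ]
        s = d_statistics(peptides)
        assert s.n_with_gt1_D <= s.n_with_ge1_D <= s.n_peptides
        assert s.n_D <= s.n_monomers
        assert (s.n_with_ge1_D, s.n_with_gt1_D) == (2, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(IsomeryError):
            d_statistics([])
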