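"""Interaction-status derivation and fate assignment."""

import pytest

from parafate import (
    ComplexRecord,
    EvidenceEdge,
    InteractionStatus,
    assign_fate,
    build_homomer_set,
    classify_pairs,
    derive_status_curated,
    derive_status_ppi,
)
from parafate.paralogs import assign_tiers, collapse_to_pairs, paralog_partner_map
from parafate.ppi import apply_filters, compile_edges, extract_paralog_edges
from parafate.types import UNASSIGNED


def _edge(a, b):
    return EvidenceEdge(*(sorted((a, b))), databases={"db1", "db2"},
                        directions={"a_as_bait", "b_as_bait"})


class TestDeriveStatusPPI:
    def test_self_edges_read_off(self):
        s = derive_status_ppi(("A", "B"), [_edge("A", "A"), _edge("B", "B")])
        assert (s.self_a, s.self_b, s.cross) == (True, True, False)

    def test_cross_edge_read_off(self):
        s = derive_status_ppi(("A", "B"), [_edge("A", "B")])
        assert (s.self_a, s.self_b, s.cross) == (False, False, True)

    def test_non_paralogous_partner_detected(self):
        partners = {"A": {"B"}, "B": {"A"}}
        s = derive_status_ppi(
            ("A", "B"), [_edge("A", "A"), _edge("B", "C")], partners
        )
        assert s.self_a and s.other_partner_b and not s.other_partner_a

    def test_paralogous_partner_does_not_count(self):
        partners = {"A": {"B"}, "B": {"A", "C"}, "C": {"B"}}
        s = derive_status_ppi(("A", "B"), [_edge("B", "C")], partners)
        assert not s.other_partner_b


class TestAssignFateExamples:
    def test_hetero_others_becomes_homo_under_flexible(self):
        s = InteractionStatus(("A", "B"), self_a=True, self_b=False,
                              other_partner_b=True)
        assert assign_fate(s, "stringent") == "hetero_others"
        assert assign_fate(s, "flexible") == "obligatory_homo"

    def test_cross_without_self_is_obligatory_hetero(self):
        s = InteractionStatus(("A", "B"), cross=True)
        assert assign_fate(s, "stringent") == "obligatory_hetero"
        assert assign_fate(s, "flexible") == "obligatory_hetero"

    def test_no_evidence_is_unassigned(self):
        s = InteractionStatus(("A", "B"))
        assert assign_fate(s, "stringent") == UNASSIGNED
        assert assign_fate(s, "flexible") == UNASSIGNED

    def test_homo_veto_blocks_both_criteria(self):
        s = InteractionStatus(("A", "B"), self_a=True, self_b=True,
                              homo_veto=True)
        assert assign_fate(s, "stringent") == UNASSIGNED
        assert assign_fate(s, "flexible") == UNASSIGNED

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            assign_fate(InteractionStatus(("A", "B")), "lenient")


class TestDeriveStatusCurated:
    def test_pdb_self_contact_gives_homomer_without_ppi(self):
        cx = ComplexRecord("C1", "PDB", {"A": 2}, contacts=[("A", "A")])
        s = derive_status_curated(("A", "B"), [cx], [])
        assert s.self_a and not s.self_b and not s.cross

    def test_cs_co_membership_needs_ppi_cross_edge(self):
        cx = ComplexRecord("C1", "CS", {"A": 1, "B": 1})
        with_edge = derive_status_curated(("A", "B"), [cx], [_edge("A", "B")])
        without = derive_status_curated(("A", "B"), [cx], [])
        assert with_edge.cross and not with_edge.self_a
        assert not without.cross

    def test_cs_stoichiometry_needs_ppi_self_edge(self):
        cx = ComplexRecord("C1", "CS", {"A": 2})
        assert not derive_status_curated(("A", "B"), [cx], []).self_a
        assert derive_status_curated(("A", "B"), [cx], [_edge("A", "A")]).self_a

    def test_c_tier_known_single_copy_blocks_homomer(self):
        cx = ComplexRecord("C1", "C", {"A": 1, "X": None})
        s = derive_status_curated(("A", "B"), [cx], [_edge("A", "A")])
        assert not s.self_a

    def test_c_tier_unknown_copy_falls_back_on_self_edge(self):
        cx = ComplexRecord("C1", "C", {"A": None, "X": None})
        s = derive_status_curated(("A", "B"), [cx], [_edge("A", "A")])
        assert s.self_a

    def test_homo_vetoed_by_ppi_cross_edge(self):
        complexes = [
            ComplexRecord("C1", "PDB", {"A": 2}, contacts=[("A", "A")]),
            ComplexRecord("C2", "PDB", {"B": 2}, contacts=[("B", "B")]),
        ]
        partners = {"A": {"B"}, "B": {"A"}}
        edges = [_edge("A", "A"), _edge("B", "B"), _edge("A", "B")]
        s = derive_status_curated(("A", "B"), complexes, edges, partners)
        assert s.self_a and s.self_b and not s.cross
        assert s.homo_veto
        assert assign_fate(s, "stringent") == UNASSIGNED
        assert assign_fate(s, "flexible") == UNASSIGNED

    def test_contacts_on_non_pdb_tier_rejected(self):
        with pytest.raises(ValueError, match="PDB"):
            ComplexRecord("C1", "CS", {"A": 2}, contacts=[("A", "A")])


class TestCriterionNesting:
    def test_nesting_on_synthetic_scenario(self, clean_scenario):
        sc = clean_scenario
        pairs = assign_tiers(collapse_to_pairs(sc.hits_b), sc.domains)
        edges = extract_paralog_edges(compile_edges(sc.ppi_b), pairs)
        levels = apply_filters(edges, sc.flagged_proteins, sc.localization)
        assignments = classify_pairs(pairs, levels, sc.complexes_b)
        by = {}
        for a in assignments:
            by[(a.pair, a.dataset, a.filter_level, a.criterion)] = a.fate
        for (pair, dataset, level, criterion), fate in by.items():
            if criterion != "stringent":
                continue
            flex = by[(pair, dataset, level, "flexible")]
            if fate == "obligatory_homo" or fate == "hetero_others":
                assert flex == "obligatory_homo"
            if fate in ("obligatory_hetero", "mixed"):
                assert flex == fate

    def test_exactly_one_label_per_context(self, clean_scenario):
        sc = clean_scenario
        pairs = assign_tiers(collapse_to_pairs(sc.hits_b), sc.domains)
        edges = extract_paralog_edges(compile_edges(sc.ppi_b), pairs)
        levels = apply_filters(edges, sc.flagged_proteins, sc.localization)
        assignments = classify_pairs(pairs, levels, sc.complexes_b)
        seen = {}
        for a in assignments:
            key = (a.pair, a.dataset, a.filter_level, a.criterion)
            assert key not in seen
            seen[key] = a.fate
        expected = len(pairs) * len(levels) * 2 * 2
        assert len(seen) == expected


def test_classify_matches_per_pair_brute_force(tiny_config):
    """Pipeline classification agrees with a direct per-pair re-derivation."""
    from parafate import generate_scenario

    sc = generate_scenario(tiny_config)
    pairs = assign_tiers(collapse_to_pairs(sc.hits_b), sc.domains)
    edges = extract_paralog_edges(compile_edges(sc.ppi_b), pairs)
    levels = apply_filters(edges, sc.flagged_proteins, sc.localization)
    assignments = classify_pairs(pairs, levels, sc.complexes_b)
    partners = paralog_partner_map(pairs)

    for a in assignments:
        level_edges = levels[a.filter_level]
        if a.dataset == "ppi":
            status = derive_status_ppi(a.pair, level_edges, partners)
        else:
            status = derive_status_curated(
                a.pair, sc.complexes_b, level_edges, partners
            )
        assert assign_fate(status, a.criterion) == a.fate


class TestBuildHomomerSet:
    def test_sources_of_homomer_evidence(self):
        edges = [_edge("A", "A")]
        complexes = [
            ComplexRecord("C1", "PDB", {"B": 2}, contacts=[("B", "B")]),
            ComplexRecord("C2", "C", {"D": None}),  # no self-edge: excluded
        ]
        assert build_homomer_set(edges, complexes) == {"A", "B"}
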