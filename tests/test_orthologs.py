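"""Reciprocal orthology links and homomer-to-heteromer transition mapping."""

from parafate import (
    DomainAnnotation,
    FateAssignment,
    HomologyHit,
    compare_orders,
    map_transitions,
    reciprocal_links,
    shared_domain_filter,
)
from parafate.orthologs import TransitionRecord, summarize_transitions
from parafate.paralogs import assign_tiers


def _hit(q, s, e):
    return HomologyHit(q, s, 35.0, 80.0, e, 200)


class TestReciprocalLinks:
    def test_mutual_subthreshold_hits_link(self):
        links = reciprocal_links([_hit("A1", "B1", 1e-10)], [_hit("B1", "A1", 1e-8)])
        assert len(links) == 1
        assert links[0].protein_a == "A1" and links[0].reciprocal

    def test_one_direction_only_fails(self):
        assert reciprocal_links([_hit("A1", "B1", 1e-10)], []) == []

    def test_above_threshold_fails(self):
        assert reciprocal_links([_hit("A1", "B1", 1e-4)],
                                [_hit("B1", "A1", 1e-4)]) == []

    def test_species_role_swap_symmetry(self):
        ab = [_hit("A1", "B1", 1e-10), _hit("A2", "B2", 1e-9)]
        ba = [_hit("B1", "A1", 1e-8), _hit("B2", "A2", 1e-7)]
        fwd = {(l.protein_a, l.protein_b) for l in reciprocal_links(ab, ba)}
        rev = {(l.protein_b, l.protein_a) for l in reciprocal_links(ba, ab)}
        assert fwd == rev

    def test_strict_best_hit_mode(self):
        # A1 hits both B1 (better) and B2; strict mode keeps only A1-B1.
        ab = [_hit("A1", "B1", 1e-20), _hit("A1", "B2", 1e-10)]
        ba = [_hit("B1", "A1", 1e-18), _hit("B2", "A1", 1e-9)]
        loose = reciprocal_links(ab, ba)
        strict = reciprocal_links(ab, ba, strict_best_hit=True)
        assert len(loose) == 2 and len(strict) == 1
        assert strict[0].protein_b == "B1"


class TestSharedDomainFilter:
    def _links(self):
        return reciprocal_links([_hit("A1", "B1", 1e-10)], [_hit("B1", "A1", 1e-8)])

    def test_shared_domain_retained(self):
        kept = shared_domain_filter(
            self._links(),
            [DomainAnnotation("A1", "D1", 1e-9), DomainAnnotation("A1", "D2", 1e-9)],
            [DomainAnnotation("B1", "D2", 1e-9)],
        )
        assert len(kept) == 1 and kept[0].shared_domains == frozenset({"D2"})

    def test_disjoint_domains_removed(self):
        assert shared_domain_filter(
            self._links(),
            [DomainAnnotation("A1", "D1", 1e-9)],
            [DomainAnnotation("B1", "D2", 1e-9)],
        ) == []

    def test_no_domains_removed(self):
        assert shared_domain_filter(self._links(), [], []) == []

    def test_insignificant_domains_do_not_rescue(self):
        assert shared_domain_filter(
            self._links(),
            [DomainAnnotation("A1", "D1", 1e-3)],
            [DomainAnnotation("B1", "D1", 1e-3)],
        ) == []


def _b_assignment(pair, fate):
    return FateAssignment(pair=pair, dataset="ppi", filter_level="f3",
                          criterion="stringent", fate=fate)


def _link_set(pairs_ab):
    ab = [_hit(a, b, 1e-10) for a, b in pairs_ab]
    ba = [_hit(b, a, 1e-10) for a, b in pairs_ab]
    return reciprocal_links(ab, ba)


class TestMapTransitions:
    def test_singleton_homomer_to_hetero_pair(self):
        links = _link_set([("E1", "Y1"), ("E1", "Y2")])
        (rec,) = map_transitions(
            links, {"E1"}, [], [_b_assignment(("Y1", "Y2"), "obligatory_hetero")]
        )
        assert rec.a_side_type == "singleton" and rec.a_ids == ("E1",)
        assert set(rec.linked_b_members) == {"Y1", "Y2"}

    def test_non_homomeric_a_protein_ignored(self):
        links = _link_set([("E1", "Y1")])
        assert map_transitions(
            links, set(), [], [_b_assignment(("Y1", "Y2"), "mixed")]
        ) == []

    def test_paralogous_a_pair_grouped_as_one_unit(self):
        links = _link_set([("E1A", "Y1"), ("E1B", "Y2")])
        a_pairs = assign_tiers({("E1A", "E1B"): (50.0, 80.0, 1e-30)})
        (rec,) = map_transitions(
            links, {"E1A", "E1B"}, a_pairs,
            [_b_assignment(("Y1", "Y2"), "mixed")],
        )
        assert rec.a_side_type == "pair" and rec.a_ids == ("E1A", "E1B")

    def test_homo_fate_b_pairs_excluded(self):
        links = _link_set([("E1", "Y1")])
        assert map_transitions(
            links, {"E1"}, [], [_b_assignment(("Y1", "Y2"), "obligatory_homo")]
        ) == []

    def test_require_both_members_flag(self):
        links = _link_set([("E1", "Y1")])  # only one member linked
        asg = [_b_assignment(("Y1", "Y2"), "obligatory_hetero")]
        assert len(map_transitions(links, {"E1"}, [], asg)) == 1
        assert map_transitions(links, {"E1"}, [], asg,
                               require_both_members=True) == []


class TestCompareOrders:
    def _rec(self):
        return TransitionRecord("singleton", ("E1",), ("Y1", "Y2"),
                                "obligatory_hetero")

    def test_homodimer_to_heterodimer_retained(self):
        rec = compare_orders(self._rec(), 2, 2)
        assert rec.order_relation == "retained"

    def test_homodimer_to_octamer_changed(self):
        rec = compare_orders(self._rec(), 2, 8)
        assert rec.order_relation == "changed"

    def test_unknown_order_is_unknown(self):
        assert compare_orders(self._rec(), 2, None).order_relation == "unknown"


def test_summary_counts_by_a_side_type():
    recs = [
        TransitionRecord("singleton", ("E1",), ("Y1", "Y2"), "mixed"),
        TransitionRecord("pair", ("E2A", "E2B"), ("Y3", "Y4"), "mixed"),
        TransitionRecord("singleton", ("E3",), ("Y5", "Y6"), "obligatory_hetero"),
    ]
    assert summarize_transitions(recs) == {"singleton": 2, "pair": 1}
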