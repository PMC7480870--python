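"""Paralog detection: BLAST parsing, pair collapsing, tier assignment."""

import pytest

from parafate import (
    DomainAnnotation,
    HomologyHit,
    TierThresholds,
    assign_tiers,
    collapse_to_pairs,
    load_ohnolog_flags,
    read_blast6,
)
from parafate.paralogs import paralog_partner_map, tier_members


def _hit(q, s, ident, cov, e=1e-20):
    return HomologyHit(q, s, ident, cov, e, 100)


def _blast6_line(q, s, ident=50.0, e=1e-20, qcovs=None, qstart=1, qend=100):
    fields = [q, s, f"{ident:.2f}", "100", "10", "0", str(qstart), str(qend),
              "1", "100", repr(e), "200.0"]
    if qcovs is not None:
        fields.append(f"{qcovs:.2f}")
    return "\t".join(fields)


class TestReadBlast6:
    def test_self_hits_dropped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast6_line("A", "A", qcovs=90.0) + "\n")
        assert read_blast6(p) == []

    def test_boundary_identity_passes_through(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast6_line("A", "B", ident=25.0, qcovs=40.0) + "\n")
        (hit,) = read_blast6(p)
        assert hit.percent_identity == 25.0
        assert hit.query_coverage == 40.0

    def test_reciprocal_hits_not_collapsed_by_parser(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "\n".join(
                [
                    _blast6_line("A", "B", qcovs=80.0),
                    _blast6_line("B", "A", qcovs=80.0),
                    _blast6_line("A", "A", qcovs=99.0),
                ]
            )
            + "\n"
        )
        assert len(read_blast6(p)) == 2

    def test_coverage_computed_from_length_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast6_line("A", "B", qstart=1, qend=100) + "\n")
        (hit,) = read_blast6(p, query_lengths={"A": 200})
        assert hit.query_coverage == pytest.approx(50.0)
        with pytest.raises(ValueError, match="length table"):
            read_blast6(p)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast6_line("A", "B", qcovs=80.0) + "\nbad\trow\n")
        with pytest.raises(ValueError, match="line 2"):
            read_blast6(p)


class TestCollapseToPairs:
    def test_smallest_e_value_wins(self):
        pairs = collapse_to_pairs(
            [_hit("A", "B", 30.0, 80.0, e=1e-10), _hit("B", "A", 32.0, 80.0, e=1e-8)]
        )
        assert pairs[("A", "B")] == (30.0, 80.0, 1e-10)

    def test_single_hit_identity(self):
        pairs = collapse_to_pairs([_hit("A", "B", 41.0, 66.0, e=1e-12)])
        assert pairs[("A", "B")] == (41.0, 66.0, 1e-12)

    def test_equal_e_values_break_on_identity(self):
        pairs = collapse_to_pairs(
            [_hit("A", "B", 30.0, 80.0, e=1e-10), _hit("B", "A", 35.0, 80.0, e=1e-10)]
        )
        assert pairs[("A", "B")][0] == 35.0


class TestAssignTiers:
    def test_inclusive_boundaries(self):
        pairs = {
            ("A", "B"): (25.0, 40.0, 1e-9),   # exactly LC
            ("C", "D"): (30.0, 50.0, 1e-9),   # exactly MC
            ("E", "F"): (40.0, 60.0, 1e-9),   # exactly HC numbers
            ("G", "H"): (24.9, 90.0, 1e-9),   # below LC identity
        }
        domains = [
            DomainAnnotation("E", "D1", 1e-9),
            DomainAnnotation("F", "D1", 1e-9),
        ]
        out = {p.key: p.tier for p in assign_tiers(pairs, domains)}
        assert out == {("A", "B"): "LC", ("C", "D"): "MC", ("E", "F"): "HC"}

    def test_hc_denied_by_domain_content(self):
        pairs = {("A", "B"): (45.0, 70.0, 1e-9)}
        domains = [
            DomainAnnotation("A", "D1", 1e-9),
            DomainAnnotation("A", "D2", 1e-9),
            DomainAnnotation("B", "D1", 1e-9),
        ]
        (pair,) = assign_tiers(pairs, domains)
        assert pair.tier == "MC"
        assert pair.same_domain_content is False

    def test_domain_copy_number_matters(self):
        # Same domain identifiers but different copy numbers deny HC.
        pairs = {("A", "B"): (45.0, 70.0, 1e-9)}
        domains = [
            DomainAnnotation("A", "D1", 1e-9),
            DomainAnnotation("A", "D1", 1e-9),
            DomainAnnotation("B", "D1", 1e-9),
        ]
        (pair,) = assign_tiers(pairs, domains)
        assert pair.tier == "MC"

    def test_insignificant_domains_ignored(self):
        # A domain at p >= 1e-5 does not participate in the content check.
        pairs = {("A", "B"): (45.0, 70.0, 1e-9)}
        domains = [
            DomainAnnotation("A", "D1", 1e-9),
            DomainAnnotation("B", "D1", 1e-9),
            DomainAnnotation("B", "D2", 1e-4),
        ]
        (pair,) = assign_tiers(pairs, domains)
        assert pair.tier == "HC"

    def test_tier_nesting_on_synthetic_hits(self, clean_scenario):
        pairs = assign_tiers(
            collapse_to_pairs(clean_scenario.hits_b), clean_scenario.domains
        )
        n = {t: len(tier_members(pairs, t)) for t in ("LC", "MC", "HC")}
        assert n["HC"] <= n["MC"] <= n["LC"]

    def test_threshold_monotonicity(self, clean_scenario):
        pairs = collapse_to_pairs(clean_scenario.hits_b)
        base = assign_tiers(pairs, clean_scenario.domains)
        raised = assign_tiers(
            pairs,
            clean_scenario.domains,
            TierThresholds(lc_identity=28.0, mc_identity=33.0, hc_identity=45.0),
        )
        for tier in ("LC", "MC", "HC"):
            assert len(tier_members(raised, tier)) <= len(tier_members(base, tier))

    def test_brute_force_oracle_equivalence(self, tiny_config):
        """Tiers agree with a direct rescan of all hits per pair."""
        from parafate import generate_scenario

        scenario = generate_scenario(tiny_config)
        hits = scenario.hits_b
        got = {
            p.key: p.tier
            for p in assign_tiers(collapse_to_pairs(hits), scenario.domains)
        }

        # Oracle: scan every hit touching the pair, keep the minimum-e-value
        # statistics, apply the thresholds literally.
        from collections import Counter

        sig = Counter()
        per_protein: dict[str, Counter] = {}
        for d in scenario.domains:
            if d.p_value < 1e-5:
                per_protein.setdefault(d.protein_id, Counter())[d.domain_id] += 1
        keys = {tuple(sorted((h.query_id, h.subject_id))) for h in hits}
        expected = {}
        for a, b in keys:
            cand = [
                h for h in hits if tuple(sorted((h.query_id, h.subject_id))) == (a, b)
            ]
            best = min(
                cand,
                key=lambda h: (h.e_value, -h.percent_identity, -h.query_coverage,
                               h.query_id),
            )
            i, c = best.percent_identity, best.query_coverage
            if i < 25 or c < 40:
                continue
            tier = "LC"
            if i >= 30 and c >= 50:
                tier = "MC"
            if tier == "MC" and i >= 40 and c >= 60:
                if per_protein.get(a, Counter()) == per_protein.get(b, Counter()):
                    tier = "HC"
            expected[(a, b)] = tier
        assert got == expected


class TestOhnologFlags:
    def test_flagging(self, tmp_path):
        pairs = assign_tiers({("A", "B"): (30.0, 60.0, 1e-9),
                              ("C", "D"): (30.0, 60.0, 1e-9)})
        p = tmp_path / "ohno.tsv"
        p.write_text("B\tA\nX\tZ\n")
        with pytest.warns(UserWarning, match="not among detected"):
            pairs = load_ohnolog_flags(p, pairs)
        flags = {q.key: q.ohnolog for q in pairs}
        assert flags == {("A", "B"): True, ("C", "D"): False}

    def test_empty_list_all_false(self, tmp_path):
        pairs = assign_tiers({("A", "B"): (30.0, 60.0, 1e-9)})
        p = tmp_path / "ohno.tsv"
        p.write_text("")
        pairs = load_ohnolog_flags(p, pairs)
        assert not pairs[0].ohnolog


def test_partner_map_is_symmetric(clean_scenario):
    from parafate import assign_tiers as at

    pairs = at(collapse_to_pairs(clean_scenario.hits_b), clean_scenario.domains)
    pm = paralog_partner_map(pairs)
    for protein, partners in pm.items():
        for q in partners:
            assert protein in pm[q]
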