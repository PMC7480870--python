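"""Cross-species mapping of homomers to heteromeric paralog pairs.

Orthology between a prokaryote-like species A and a eukaryote-like species
B is inferred from reciprocal inter-species homology searches: a link is
kept when sub-threshold hits (e-value < 1e-5) exist in both directions.  A
``strict_best_hit`` mode additionally demands that each protein is the
other's best hit.  Links are then restricted to protein pairs sharing at
least one significant Pfam-style domain.

A transition record pairs a homomeric species-A unit — either a singleton
homomer or a paralogous pair of homomers — with a species-B paralogous pair
whose fate is obligatory-heteromer or mixed.  By parsimony such records
reflect duplication and divergence of an ancestral homomer into heteromeric
paralogs.  When stoichiometry is available the ancestral and derived
oligomeric orders (total subunit counts) are compared.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .types import (
    MIXED,
    OBLIGATORY_HETERO,
    DomainAnnotation,
    FateAssignment,
    HomologyHit,
    ParalogPair,
    pair_key,
)
from .paralogs import DOMAIN_P_CUTOFF

E_VALUE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class OrthologLink:
    protein_a: str  # species A
    protein_b: str  # species B
    e_value_fwd: float
    e_value_rev: float
    reciprocal: bool = True
    shared_domains: frozenset[str] = frozenset()


@dataclass
class TransitionRecord:
    """One (species-A homomeric unit, species-B heteromeric pair) mapping."""

    a_side_type: str  # "singleton" | "pair"
    a_ids: tuple[str, ...]
    b_pair: tuple[str, str]
    b_fate: str
    a_order: int | None = None
    b_order: int | None = None
    order_relation: str = "unknown"  # retained | changed | unknown
    linked_b_members: tuple[str, ...] = field(default_factory=tuple)


def _best_hits(hits: list[HomologyHit]) -> dict[str, str]:
    """Per query, the subject of the minimum-e-value hit (deterministic ties)."""
    best: dict[str, tuple] = {}
    for h in hits:
        rank = (h.e_value, -h.percent_identity, h.subject_id)
        if h.query_id not in best or rank < best[h.query_id][0]:
            best[h.query_id] = (rank, h.subject_id)
    return {q: v[1] for q, v in best.items()}


def reciprocal_links(
    hits_ab: list[HomologyHit],
    hits_ba: list[HomologyHit],
    e_threshold: float = E_VALUE_THRESHOLD,
    strict_best_hit: bool = False,
) -> list[OrthologLink]:
    """Cross-species links with sub-threshold hits in both directions.

    Reciprocity means mutual presence of hits below ``e_threshold``; with
    ``strict_best_hit`` each protein must also be the other's best hit.
    """
    fwd: dict[tuple[str, str], float] = {}
    for h in hits_ab:
        if h.e_value < e_threshold:
            k = (h.query_id, h.subject_id)
            fwd[k] = min(fwd.get(k, float("inf")), h.e_value)
    rev: dict[tuple[str, str], float] = {}
    for h in hits_ba:
        if h.e_value < e_threshold:
            k = (h.subject_id, h.query_id)  # keyed (A, B) like fwd
            rev[k] = min(rev.get(k, float("inf")), h.e_value)

    links = []
    for (a, b) in sorted(set(fwd) & set(rev)):
        links.append(
            OrthologLink(
                protein_a=a,
                protein_b=b,
                e_value_fwd=fwd[(a, b)],
                e_value_rev=rev[(a, b)],
            )
        )
    if strict_best_hit:
        best_ab = _best_hits([h for h in hits_ab if h.e_value < e_threshold])
        best_ba = _best_hits([h for h in hits_ba if h.e_value < e_threshold])
        links = [
            l
            for l in links
            if best_ab.get(l.protein_a) == l.protein_b
            and best_ba.get(l.protein_b) == l.protein_a
        ]
    return links


def shared_domain_filter(
    links: list[OrthologLink],
    domains_a: list[DomainAnnotation],
    domains_b: list[DomainAnnotation],
    p_cutoff: float = DOMAIN_P_CUTOFF,
) -> list[OrthologLink]:
    """Keep links whose proteins share at least one significant domain."""

    def per_protein(domains: list[DomainAnnotation]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d in domains:
            if d.p_value < p_cutoff:
                out.setdefault(d.protein_id, set()).add(d.domain_id)
        return out

    dom_a = per_protein(domains_a)
    dom_b = per_protein(domains_b)
    kept = []
    for l in links:
        shared = dom_a.get(l.protein_a, set()) & dom_b.get(l.protein_b, set())
        if shared:
            kept.append(
                OrthologLink(
                    protein_a=l.protein_a,
                    protein_b=l.protein_b,
                    e_value_fwd=l.e_value_fwd,
                    e_value_rev=l.e_value_rev,
                    shared_domains=frozenset(shared),
                )
            )
    return kept


def map_transitions(
    links: list[OrthologLink],
    a_homomers: set[str],
    a_pairs: list[ParalogPair],
    b_assignments: list[FateAssignment],
    require_both_members: bool = False,
    accept_list: set[tuple[str, str]] | None = None,
) -> list[TransitionRecord]:
    """Pair species-A homomeric units with heteromeric species-B pairs.

    ``b_assignments`` should be one context (typically the stringent
    criterion on the fully filtered PPI dataset at the most inclusive
    paralog tier); only pairs with fate obligatory-heteromer or mixed are
    considered.  By default one linked B member suffices;
    ``require_both_members`` demands links from both.  ``accept_list``
    optionally restricts (A protein, B protein) links to a curated set,
    standing in for manual same-function checking.
    """
    link_map: dict[str, set[str]] = {}  # B protein -> linked A homomers
    for l in links:
        if accept_list is not None and (l.protein_a, l.protein_b) not in accept_list:
            continue
        if l.protein_a in a_homomers:
            link_map.setdefault(l.protein_b, set()).add(l.protein_a)

    a_pair_of: dict[str, tuple[str, str]] = {}
    for p in a_pairs:
        a_pair_of[p.protein_a] = p.key
        a_pair_of[p.protein_b] = p.key

    records: list[TransitionRecord] = []
    seen: set[tuple] = set()
    for assignment in sorted(b_assignments, key=lambda x: x.pair):
        if assignment.fate not in (OBLIGATORY_HETERO, MIXED):
            continue
        b1, b2 = assignment.pair
        linked_1 = link_map.get(b1, set())
        linked_2 = link_map.get(b2, set())
        if require_both_members:
            candidates = linked_1 & linked_2
        else:
            candidates = linked_1 | linked_2
        # Group candidate A homomers into units: paralogous pair or singleton.
        units: dict[tuple[str, ...], list[str]] = {}
        for a in sorted(candidates):
            unit = a_pair_of.get(a, (a,))
            units.setdefault(tuple(unit), []).append(a)
        for unit in sorted(units):
            dedup = (unit, assignment.pair)
            if dedup in seen:
                continue
            seen.add(dedup)
            linked_members = tuple(
                m for m in (b1, b2) if link_map.get(m, set()) & set(units[unit])
            )
            records.append(
                TransitionRecord(
                    a_side_type="pair" if len(unit) == 2 else "singleton",
                    a_ids=unit,
                    b_pair=assignment.pair,
                    b_fate=assignment.fate,
                    linked_b_members=linked_members,
                )
            )
    return records


def compare_orders(
    record: TransitionRecord,
    a_order: int | None,
    b_order: int | None,
) -> TransitionRecord:
    """Fill in oligomeric orders and whether the order was retained.

    ``retained`` requires both orders known and equal; ``changed`` both
    known and unequal; anything else is ``unknown``.
    """
    record.a_order = a_order
    record.b_order = b_order
    if a_order is not None and b_order is not None:
        record.order_relation = "retained" if a_order == b_order else "changed"
    else:
        record.order_relation = "unknown"
    return record


def summarize_transitions(records: list[TransitionRecord]) -> Counter:
    """Counts of records by A-side type (singleton vs paralogous pair)."""
    return Counter(r.a_side_type for r in records)
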