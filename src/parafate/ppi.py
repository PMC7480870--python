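"""Multi-database PPI compilation and the three successive quality filters.

Raw interaction records from several source databases are first reduced to
undirected evidence edges, keeping only experimentally observed records
(predicted and text-mining entries are dropped at compilation).  Three
filters are then applied in order:

1. remove every edge touching a flagged mobile-element (retrotransposon)
   protein;
2. keep an edge only if it was reported in at least two databases and, for
   non-self edges, observed with both proteins as bait and as prey;
3. remove non-self edges between proteins annotated to disjoint subcellular
   compartments.

Self-edges are the evidence for homomers, so filter 2 applies only its
database-count condition to them (a self-edge cannot have two distinct
bait/prey roles) and filter 3 never removes them.  Proteins with no
localization data are treated as compatible with every compartment.
"""

from __future__ import annotations

from .types import (
    EVIDENCE_CLASSES,
    EvidenceEdge,
    ParalogPair,
    RawPPIRecord,
    pair_key,
)

BOTH_DIRECTIONS = {"a_as_bait", "b_as_bait"}


def compile_edges(records: list[RawPPIRecord]) -> list[EvidenceEdge]:
    """Aggregate raw records into undirected evidence edges.

    Records whose evidence class is not ``experimental`` are dropped;
    unknown evidence classes raise.  Databases, bait/prey directions and
    method classes are unioned per unordered pair.
    """
    edges: dict[tuple[str, str], EvidenceEdge] = {}
    for rec in records:
        if rec.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(
                f"record {rec.interactor_a}-{rec.interactor_b}: unknown "
                f"evidence class {rec.evidence_class!r}"
            )
        if rec.evidence_class != "experimental":
            continue
        a, b = pair_key(rec.interactor_a, rec.interactor_b)
        edge = edges.setdefault(
            (a, b), EvidenceEdge(protein_a=a, protein_b=b)
        )
        edge.databases.add(rec.source_db)
        edge.method_classes.add(rec.method_class)
        if a == b:
            edge.directions.add("a_as_bait")
        elif rec.bait_id is not None:
            if rec.bait_id not in (a, b):
                raise ValueError(
                    f"record {a}-{b}: bait {rec.bait_id!r} is not an interactor"
                )
            edge.directions.add("a_as_bait" if rec.bait_id == a else "b_as_bait")
    return [edges[k] for k in sorted(edges)]


def filter1_mobile_elements(
    edges: list[EvidenceEdge], flagged_proteins: set[str]
) -> list[EvidenceEdge]:
    """Drop every edge touching a flagged mobile-element protein."""
    return [
        e
        for e in edges
        if e.protein_a not in flagged_proteins and e.protein_b not in flagged_proteins
    ]


def filter2_evidence(edges: list[EvidenceEdge]) -> list[EvidenceEdge]:
    """Keep edges reported in >= 2 databases and seen in both bait/prey roles.

    For self-edges only the database-count condition applies.
    """
    out = []
    for e in edges:
        if len(e.databases) < 2:
            continue
        if not e.is_self and e.directions != BOTH_DIRECTIONS:
            continue
        out.append(e)
    return out


def filter3_colocalization(
    edges: list[EvidenceEdge], localization: dict[str, set[str]]
) -> list[EvidenceEdge]:
    """Remove non-self edges between proteins in disjoint compartments.

    An edge is removed only when both proteins have at least one compartment
    annotation and the annotation sets do not intersect; missing annotation
    never removes an edge.
    """
    out = []
    for e in edges:
        if not e.is_self:
            loc_a = localization.get(e.protein_a, set())
            loc_b = localization.get(e.protein_b, set())
            if loc_a and loc_b and not (loc_a & loc_b):
                continue
        out.append(e)
    return out


def extract_paralog_edges(
    edges: list[EvidenceEdge], pairs: list[ParalogPair]
) -> list[EvidenceEdge]:
    """Edges with at least one endpoint in the detected paralog set.

    Edges between a paralog and a non-paralog are kept; they are the
    evidence for gain of new interaction partners.
    """
    paralog_proteins: set[str] = set()
    for p in pairs:
        paralog_proteins.add(p.protein_a)
        paralog_proteins.add(p.protein_b)
    return [
        e
        for e in edges
        if e.protein_a in paralog_proteins or e.protein_b in paralog_proteins
    ]


def apply_filters(
    edges: list[EvidenceEdge],
    flagged_proteins: set[str] | None = None,
    localization: dict[str, set[str]] | None = None,
) -> dict[str, list[EvidenceEdge]]:
    """Run the three-filter cascade; returns every level keyed raw/f1/f2/f3.

    When no localization table is supplied the f3 level equals f2 (the
    colocalization filter degrades to a no-op).
    """
    f1 = filter1_mobile_elements(edges, flagged_proteins or set())
    f2 = filter2_evidence(f1)
    f3 = filter3_colocalization(f2, localization) if localization is not None else f2
    return {"raw": edges, "f1": f1, "f2": f2, "f3": f3}


def subset_non_baitprey_methods(
    records: list[RawPPIRecord],
    localization: dict[str, set[str]] | None = None,
) -> list[EvidenceEdge]:
    """Edges supported exclusively by methods other than two-hybrid/pull-down.

    Used to check that the bait-and-prey demand of filter 2 does not bias
    the fate distribution: pairs with any two-hybrid or pull-down record are
    excluded, then the database-count and colocalization filters (but not
    the direction filter, which these methods cannot satisfy) are applied.
    """
    edges = compile_edges(records)
    only_other = [e for e in edges if e.method_classes == {"other"}]
    kept = [e for e in only_other if len(e.databases) >= 2]
    if localization is not None:
        kept = filter3_colocalization(kept, localization)
    return kept
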