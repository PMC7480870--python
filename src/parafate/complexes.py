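"""Counting curated complexes by the divergence fates of their paralog pairs.

A complex is attributed to a fate when it contains at least one paralogous
pair assigned that fate.  Cross-interacting fates (obligatory heteromer,
mixed) require both pair members in the complex; the homomer-side fates
(obligatory homomer, hetero-others) count a complex when it contains a pair
member, since each paralog's own homomeric complex is the relevant object.
A complex holding pairs of k distinct fates contributes to k cells, so the
per-fate counts need not sum to the number of complexes.
"""

from __future__ import annotations

from .types import (
    FATES,
    HETERO_OTHERS,
    MIXED,
    OBLIGATORY_HETERO,
    OBLIGATORY_HOMO,
    ComplexRecord,
    FateAssignment,
    ParalogPair,
)


def count_complexes_by_fate(
    complexes: list[ComplexRecord],
    assignments: list[FateAssignment],
) -> dict[str, int]:
    """Number of unique complexes containing >= 1 pair of each fate.

    ``assignments`` should come from the curated dataset at one fixed
    (filter level, criterion) context; mixing contexts double-counts.
    """
    contexts = {(a.dataset, a.filter_level, a.criterion) for a in assignments}
    if len(contexts) > 1:
        raise ValueError(
            f"assignments span multiple (dataset, filter, criterion) contexts: "
            f"{sorted(contexts)}"
        )
    per_fate: dict[str, set[str]] = {fate: set() for fate in FATES}
    for a in assignments:
        if a.fate not in per_fate:
            continue
        pa, pb = a.pair
        for cx in complexes:
            if a.fate in (OBLIGATORY_HETERO, MIXED):
                if pa in cx.members and pb in cx.members:
                    per_fate[a.fate].add(cx.complex_id)
            elif a.fate in (OBLIGATORY_HOMO, HETERO_OTHERS):
                if pa in cx.members or pb in cx.members:
                    per_fate[a.fate].add(cx.complex_id)
    return {fate: len(ids) for fate, ids in per_fate.items()}


def count_paralog_membership(
    complexes: list[ComplexRecord], pairs: list[ParalogPair]
) -> int:
    """Number of distinct complexes containing at least one paralogous protein."""
    paralog_proteins: set[str] = set()
    for p in pairs:
        paralog_proteins.add(p.protein_a)
        paralog_proteins.add(p.protein_b)
    return sum(
        1 for cx in complexes if paralog_proteins.intersection(cx.members)
    )


def complex_order(cx: ComplexRecord) -> int | None:
    """Oligomeric order: total subunit count, None if any copy number unknown."""
    total = 0
    for copies in cx.members.values():
        if copies is None:
            return None
        total += copies
    return total
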