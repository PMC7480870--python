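"""Fate assignment for paralogous pairs.

Each pair's interaction status is a triple of booleans — does each paralog
self-interact, and do the two cross-interact — plus flags recording whether
either paralog has a non-paralogous interaction partner.  The status maps
onto four divergence fates:

* obligatory homomer:   no cross-interaction, self-interaction retained
  (both paralogs under the stringent criterion, at least one under the
  flexible criterion);
* obligatory heteromer: cross-interaction, neither self-interacts;
* mixed homo/hetero:    cross-interaction plus at least one self-interaction
  (a statistical mixture of homo- and hetero-complexes);
* hetero-others:        no cross-interaction, exactly one paralog keeps the
  homomer while the other has gained a non-paralogous partner.  Emitted by
  the stringent criterion only; the flexible criterion absorbs every
  no-cross case with at least one self-interaction into obligatory homomer.

Status can be read either from a filtered PPI edge set or from curated
complex records (tiers C, CS, PDB), with the PPI network supplying the
physical-interaction cross-checks that the lower complex tiers require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import (
    HETERO_OTHERS,
    MIXED,
    OBLIGATORY_HETERO,
    OBLIGATORY_HOMO,
    UNASSIGNED,
    ComplexRecord,
    EvidenceEdge,
    FateAssignment,
    InteractionStatus,
    ParalogPair,
    pair_key,
)
from .paralogs import paralog_partner_map


@dataclass
class EdgeIndex:
    """Constant-time lookups over one edge set."""

    keys: set[tuple[str, str]] = field(default_factory=set)
    neighbours: dict[str, set[str]] = field(default_factory=dict)
    self_proteins: set[str] = field(default_factory=set)

    @classmethod
    def from_edges(cls, edges: list[EvidenceEdge]) -> "EdgeIndex":
        idx = cls()
        for e in edges:
            idx.keys.add(e.key)
            idx.neighbours.setdefault(e.protein_a, set()).add(e.protein_b)
            idx.neighbours.setdefault(e.protein_b, set()).add(e.protein_a)
            if e.is_self:
                idx.self_proteins.add(e.protein_a)
        return idx


@dataclass
class _Membership:
    tier: str
    copies: int | None
    self_contact: bool


@dataclass
class ComplexIndex:
    """Per-protein membership and contact lookups over one complex set."""

    memberships: dict[str, list[_Membership]] = field(default_factory=dict)
    co_members: set[tuple[str, str]] = field(default_factory=set)  # CS/C tiers
    pdb_contacts: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_complexes(cls, complexes: list[ComplexRecord]) -> "ComplexIndex":
        idx = cls()
        for cx in complexes:
            contacts = set(cx.contacts)
            for protein, copies in cx.members.items():
                idx.memberships.setdefault(protein, []).append(
                    _Membership(cx.tier, copies, (protein, protein) in contacts)
                )
            members = sorted(cx.members)
            if cx.tier == "PDB":
                idx.pdb_contacts.update(contacts)
            else:
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        idx.co_members.add((a, b))
        return idx

    def is_homomer(self, protein: str, self_edge_proteins: set[str]) -> bool:
        """Tier-specific homomer rule, any complex sufficing.

        PDB: copy number >= 2 plus a structural self-contact.  CS: copy
        number >= 2 plus a PPI self-edge.  C: membership plus a PPI
        self-edge; an explicitly known copy number below 2 rules that
        complex out, an unknown one falls back on the self-edge alone.
        """
        for m in self.memberships.get(protein, []):
            if m.tier == "PDB":
                if (m.copies or 0) >= 2 and m.self_contact:
                    return True
            elif m.tier == "CS":
                if (m.copies or 0) >= 2 and protein in self_edge_proteins:
                    return True
            else:  # C
                if m.copies is not None and m.copies < 2:
                    continue
                if protein in self_edge_proteins:
                    return True
        return False


def derive_status_ppi(
    pair: tuple[str, str],
    edges: list[EvidenceEdge] | None = None,
    paralog_partners: dict[str, set[str]] | None = None,
    *,
    index: EdgeIndex | None = None,
) -> InteractionStatus:
    """Read a pair's interaction status off one filtered PPI edge set.

    ``paralog_partners`` is the analysis-wide paralogy map (most inclusive
    tier): a partner only counts as an "other", non-paralogous partner if it
    is not a detected paralog of the protein and not the protein itself.
    """
    if index is None:
        index = EdgeIndex.from_edges(edges or [])
    a, b = pair_key(*pair)
    partners = paralog_partners or {}

    def has_other_partner(x: str) -> bool:
        own_paralogs = partners.get(x, set())
        return any(
            y != x and y not in own_paralogs
            for y in index.neighbours.get(x, set())
        )

    return InteractionStatus(
        pair=(a, b),
        self_a=a in index.self_proteins,
        self_b=b in index.self_proteins,
        cross=(a, b) in index.keys and a != b,
        other_partner_a=has_other_partner(a),
        other_partner_b=has_other_partner(b),
    )


def assign_fate(status: InteractionStatus, criterion: str) -> str:
    """Map an interaction status to a divergence fate under one criterion."""
    if criterion not in ("stringent", "flexible"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    s_a, s_b, cross = status.self_a, status.self_b, status.cross
    if cross:
        if not s_a and not s_b:
            return OBLIGATORY_HETERO
        return MIXED
    # No cross-interaction from here on.
    if criterion == "flexible":
        if s_a or s_b:
            return UNASSIGNED if status.homo_veto else OBLIGATORY_HOMO
        return UNASSIGNED
    if s_a and s_b:
        return UNASSIGNED if status.homo_veto else OBLIGATORY_HOMO
    if s_a != s_b:
        # Exactly one self-interacts; hetero-others requires the gained
        # partner to sit on the paralog that lost the homomer.
        other_on_nonself = (
            status.other_partner_b if s_a else status.other_partner_a
        )
        if other_on_nonself:
            return HETERO_OTHERS
    return UNASSIGNED


def derive_status_curated(
    pair: tuple[str, str],
    complexes: list[ComplexRecord] | None = None,
    filtered_edges: list[EvidenceEdge] | None = None,
    paralog_partners: dict[str, set[str]] | None = None,
    *,
    complex_index: ComplexIndex | None = None,
    edge_index: EdgeIndex | None = None,
) -> InteractionStatus:
    """Read a pair's status from curated complexes plus PPI cross-checks.

    PDB tier: self-interaction needs copy number >= 2 and a structural
    self-contact; cross-interaction needs an inter-subunit contact between
    the paralogs.  CS and C tiers predict inter-subunit interactions from
    the PPI network: self-interaction needs the tier's stoichiometry rule
    plus a PPI self-edge, cross-interaction needs complex co-membership
    plus a PPI cross-edge.  A pair that would be called an obligatory
    homomer but cross-interacts in the filtered PPI network is vetoed
    (``assign_fate`` leaves it unassigned).
    """
    if complex_index is None:
        complex_index = ComplexIndex.from_complexes(complexes or [])
    if edge_index is None:
        edge_index = EdgeIndex.from_edges(filtered_edges or [])
    a, b = pair_key(*pair)
    ppi_cross = (a, b) in edge_index.keys and a != b

    self_a = complex_index.is_homomer(a, edge_index.self_proteins)
    self_b = complex_index.is_homomer(b, edge_index.self_proteins)
    cross = ((a, b) in complex_index.pdb_contacts and a != b) or (
        (a, b) in complex_index.co_members and ppi_cross
    )

    status = InteractionStatus(
        pair=(a, b), self_a=self_a, self_b=self_b, cross=cross
    )
    if not cross and (self_a or self_b) and ppi_cross:
        status.homo_veto = True
    # Other-partner evidence still comes from the PPI network: gained
    # partners generally sit outside any curated complex of the pair.
    ppi_status = derive_status_ppi(
        (a, b), paralog_partners=paralog_partners, index=edge_index
    )
    status.other_partner_a = ppi_status.other_partner_a
    status.other_partner_b = ppi_status.other_partner_b
    return status


def classify_pairs(
    pairs: list[ParalogPair],
    edge_sets_by_filter: dict[str, list[EvidenceEdge]],
    complexes: list[ComplexRecord] | None = None,
    criteria: tuple[str, ...] = ("stringent", "flexible"),
    datasets: tuple[str, ...] = ("ppi", "curated"),
) -> list[FateAssignment]:
    """One fate per (pair x dataset x filter level x criterion).

    Cross- and self-evidence are read from the same filter level being
    evaluated, in both PPI and curated mode, so stringency axes stay
    comparable.  Unassigned pairs are recorded explicitly; downstream
    reporting excludes them from fate-fraction denominators.
    """
    partners = paralog_partner_map(pairs)
    complex_index = ComplexIndex.from_complexes(complexes or [])
    out: list[FateAssignment] = []
    sorted_pairs = sorted(pairs, key=lambda q: q.key)
    for level, edges in edge_sets_by_filter.items():
        edge_index = EdgeIndex.from_edges(edges)
        for p in sorted_pairs:
            for dataset in datasets:
                if dataset == "ppi":
                    status = derive_status_ppi(
                        p.key, paralog_partners=partners, index=edge_index
                    )
                elif dataset == "curated":
                    status = derive_status_curated(
                        p.key,
                        paralog_partners=partners,
                        complex_index=complex_index,
                        edge_index=edge_index,
                    )
                else:
                    raise ValueError(f"unknown dataset: {dataset!r}")
                for criterion in criteria:
                    out.append(
                        FateAssignment(
                            pair=p.key,
                            dataset=dataset,
                            filter_level=level,
                            criterion=criterion,
                            fate=assign_fate(status, criterion),
                            tier=p.tier,
                            evidence=status,
                        )
                    )
    return out


def build_homomer_set(
    edges: list[EvidenceEdge], complexes: list[ComplexRecord] | None = None
) -> set[str]:
    """All proteins with homomer evidence: PPI self-edge or curated-complex rule."""
    edge_index = EdgeIndex.from_edges(edges)
    homomers = set(edge_index.self_proteins)
    complex_index = ComplexIndex.from_complexes(complexes or [])
    for protein in complex_index.memberships:
        if complex_index.is_homomer(protein, edge_index.self_proteins):
            homomers.add(protein)
    return homomers
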