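"""Core record types shared across the pipeline.

The analysis revolves around five kinds of objects: proteins, paralogous
pairs, evidence-aggregated PPI edges, curated complex records, and fate
assignments.  All pair-valued keys are canonicalised as sorted 2-tuples so
that unordered identity holds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# The four divergence fates of a duplicated homomer, plus the explicit
# "no decision" label for pairs lacking usable interaction evidence.
OBLIGATORY_HOMO = "obligatory_homo"
OBLIGATORY_HETERO = "obligatory_hetero"
MIXED = "mixed"
HETERO_OTHERS = "hetero_others"
UNASSIGNED = "unassigned"

FATES = (OBLIGATORY_HOMO, OBLIGATORY_HETERO, MIXED, HETERO_OTHERS)
ALL_LABELS = FATES + (UNASSIGNED,)

TIERS = ("LC", "MC", "HC")
COMPLEX_TIERS = ("C", "CS", "PDB")
CRITERIA = ("stringent", "flexible")
FILTER_LEVELS = ("raw", "f1", "f2", "f3")
DATASETS = ("ppi", "curated")

METHOD_CLASSES = ("two_hybrid", "pulldown", "other")
EVIDENCE_CLASSES = ("experimental", "predicted", "text_mining")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair key (works for self-pairs, a == b)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identity, species, and the annotations the filters use."""

    protein_id: str
    species: str
    length: int = 0
    compartments: frozenset[str] = field(default_factory=frozenset)
    mobile_element: bool = False


@dataclass(frozen=True)
class HomologyHit:
    """A single directed intra- or inter-species homology hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    e_value: float
    alignment_length: int


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain call on a protein with its assignment p-value."""

    protein_id: str
    domain_id: str
    p_value: float


@dataclass
class ParalogPair:
    """An unordered same-species pair with its best hit statistics and tier.

    ``tier`` stores the highest attained confidence level; tier membership
    is inclusive (an HC pair is also an MC and an LC pair).
    """

    protein_a: str
    protein_b: str
    best_identity: float
    best_coverage: float
    best_e_value: float
    tier: str
    same_domain_content: bool | None = None
    ohnolog: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.protein_a, self.protein_b)


@dataclass(frozen=True)
class RawPPIRecord:
    """One interaction observation as reported by a source database."""

    interactor_a: str
    interactor_b: str
    source_db: str
    bait_id: str | None = None
    prey_id: str | None = None
    method_class: str = "other"
    evidence_class: str = "experimental"


@dataclass
class EvidenceEdge:
    """An undirected PPI edge aggregating all observations of one pair.

    ``protein_a <= protein_b``; self-edges have ``protein_a == protein_b``
    and carry the single direction ``a_as_bait`` by construction.
    """

    protein_a: str
    protein_b: str
    databases: set[str] = field(default_factory=set)
    directions: set[str] = field(default_factory=set)
    method_classes: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass
class ComplexRecord:
    """A curated complex at tier C, CS or PDB.

    ``members`` maps protein id to copy number; ``None`` means the copy
    number is unknown (allowed only at tier C).  ``contacts`` lists
    unordered inter-subunit contact pairs and is populated only at the PDB
    tier, where it comes from structure-derived interface data.
    """

    complex_id: str
    tier: str
    members: dict[str, int | None]
    contacts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in COMPLEX_TIERS:
            raise ValueError(f"unknown complex tier: {self.tier!r}")
        if self.contacts and self.tier != "PDB":
            raise ValueError(
                f"complex {self.complex_id}: contact list only valid at PDB tier"
            )
        if self.tier in ("CS", "PDB"):
            unknown = [p for p, c in self.members.items() if c is None]
            if unknown:
                raise ValueError(
                    f"complex {self.complex_id}: tier {self.tier} requires known "
                    f"copy numbers, missing for {sorted(unknown)}"
                )
        self.contacts = [pair_key(a, b) for a, b in self.contacts]


@dataclass
class InteractionStatus:
    """The boolean interaction evidence for one paralogous pair.

    ``homo_veto`` is set in curated mode when the pair would qualify as an
    obligatory homomer from complex data but shows a cross-interaction in
    the filtered PPI network; such pairs are left unassigned rather than
    called homomeric.
    """

    pair: tuple[str, str]
    self_a: bool = False
    self_b: bool = False
    cross: bool = False
    other_partner_a: bool = False
    other_partner_b: bool = False
    homo_veto: bool = False


@dataclass
class FateAssignment:
    """A pair's divergence fate in one (dataset, filter level, criterion) context."""

    pair: tuple[str, str]
    dataset: str
    filter_level: str
    criterion: str
    fate: str
    tier: str = "LC"
    evidence: InteractionStatus | None = None
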