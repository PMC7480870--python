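"""Paralogous-pair detection from all-vs-all homology hit tables.

Hits come in as BLAST tabular output (outfmt 6).  Pairs are collapsed to
their best hit and then placed into three inclusive confidence tiers:

* LC (low confidence):    >= 25% identity and >= 40% query coverage
* MC (medium confidence): >= 30% identity and >= 50% query coverage
* HC (high confidence):   >= 40% identity, >= 60% query coverage, and
  identical significant-domain content

A domain counts as significant when its assignment p-value is below 1e-5;
the HC domain check compares the multisets of significant domain
identifiers of the two proteins, so copy number matters.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .types import DomainAnnotation, HomologyHit, ParalogPair, pair_key

DOMAIN_P_CUTOFF = 1e-5

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class TierThresholds:
    """Identity/coverage thresholds per tier (all inclusive, percent units)."""

    lc_identity: float = 25.0
    lc_coverage: float = 40.0
    mc_identity: float = 30.0
    mc_coverage: float = 50.0
    hc_identity: float = 40.0
    hc_coverage: float = 60.0
    domain_p_cutoff: float = DOMAIN_P_CUTOFF
    hc_requires_identical_domains: bool = True

    def __post_init__(self) -> None:
        if not (self.lc_identity <= self.mc_identity <= self.hc_identity):
            raise ValueError("identity thresholds must be ordered LC <= MC <= HC")
        if not (self.lc_coverage <= self.mc_coverage <= self.hc_coverage):
            raise ValueError("coverage thresholds must be ordered LC <= MC <= HC")

    def minimums(self, tier: str) -> tuple[float, float]:
        return {
            "LC": (self.lc_identity, self.lc_coverage),
            "MC": (self.mc_identity, self.mc_coverage),
            "HC": (self.hc_identity, self.hc_coverage),
        }[tier]


def read_blast6(
    path,
    query_lengths: dict[str, int] | None = None,
) -> list[HomologyHit]:
    """Parse a 12-column BLAST outfmt-6 table into homology hits.

    Self-hits (query == subject) are dropped.  Query coverage is taken from
    an optional 13th column (qcovs, percent); without it, the coverage is
    computed as the aligned query span over the query length, which requires
    ``query_lengths``.

    Raises ``ValueError`` on malformed rows (with the line number) and when
    coverage must be computed but no length table was supplied.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 or 13 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if qseqid == sseqid:
                continue
            if len(fields) == 13:
                coverage = float(fields[12])
            else:
                if query_lengths is None:
                    raise ValueError(
                        f"{path}: line {lineno}: no qcovs column and no query "
                        "length table supplied; cannot compute query coverage"
                    )
                try:
                    qlen = query_lengths[qseqid]
                except KeyError:
                    raise ValueError(
                        f"{path}: line {lineno}: query {qseqid!r} missing from "
                        "length table"
                    ) from None
                coverage = 100.0 * (abs(qend - qstart) + 1) / qlen
            hits.append(
                HomologyHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    percent_identity=pident,
                    query_coverage=coverage,
                    e_value=evalue,
                    alignment_length=length,
                )
            )
    return hits


def collapse_to_pairs(
    hits: list[HomologyHit],
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Reduce directed hits to one (identity, coverage, e-value) per unordered pair.

    The representative hit is the one with the smallest e-value; ties break
    by higher identity, then higher coverage, then by lexicographic query id
    so the choice is deterministic regardless of input order.
    """
    best: dict[tuple[str, str], tuple] = {}
    for h in hits:
        key = pair_key(h.query_id, h.subject_id)
        rank = (h.e_value, -h.percent_identity, -h.query_coverage, h.query_id)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, (h.percent_identity, h.query_coverage, h.e_value))
    return {k: v[1] for k, v in sorted(best.items())}


def significant_domains(
    domains: list[DomainAnnotation],
    p_cutoff: float = DOMAIN_P_CUTOFF,
) -> dict[str, Counter]:
    """Per-protein multiset of domain ids passing the significance cutoff."""
    out: dict[str, Counter] = {}
    for d in domains:
        if d.p_value < p_cutoff:
            out.setdefault(d.protein_id, Counter())[d.domain_id] += 1
    return out


def assign_tiers(
    pairs: dict[tuple[str, str], tuple[float, float, float]],
    domains: list[DomainAnnotation] | None = None,
    thresholds: TierThresholds | None = None,
    exclude: set[tuple[str, str]] | None = None,
) -> list[ParalogPair]:
    """Label each collapsed pair with its highest attained confidence tier.

    Pairs below the LC thresholds are discarded.  HC additionally requires
    the two proteins' significant-domain multisets to be identical; a pair
    meeting the HC identity/coverage numbers but failing the domain check
    stays at MC.  ``exclude`` is an optional curation list of pairs to drop
    outright (stands in for manual inspection of putative paralogs).
    """
    thresholds = thresholds or TierThresholds()
    dom = (
        significant_domains(domains, thresholds.domain_p_cutoff)
        if domains is not None
        else None
    )
    exclude = exclude or set()

    out: list[ParalogPair] = []
    for (a, b), (ident, cov, evalue) in sorted(pairs.items()):
        if pair_key(a, b) in exclude:
            continue
        lc_i, lc_c = thresholds.minimums("LC")
        if ident < lc_i or cov < lc_c:
            continue
        tier = "LC"
        mc_i, mc_c = thresholds.minimums("MC")
        if ident >= mc_i and cov >= mc_c:
            tier = "MC"
        same_content: bool | None = None
        if dom is not None:
            same_content = dom.get(a, Counter()) == dom.get(b, Counter())
        hc_i, hc_c = thresholds.minimums("HC")
        if tier == "MC" and ident >= hc_i and cov >= hc_c:
            if not thresholds.hc_requires_identical_domains or same_content:
                tier = "HC"
        out.append(
            ParalogPair(
                protein_a=a,
                protein_b=b,
                best_identity=ident,
                best_coverage=cov,
                best_e_value=evalue,
                tier=tier,
                same_domain_content=same_content,
            )
        )
    return out


def load_ohnolog_flags(path, pairs: list[ParalogPair]) -> list[ParalogPair]:
    """Flag pairs present in a two-column whole-genome-duplication pair list.

    Purely annotative; tiers are unaffected.  Pair ids in the list that do
    not correspond to any detected pair produce a warning, not an error.
    """
    listed: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two tab-separated columns")
            listed.add(pair_key(parts[0], parts[1]))
    known = {p.key for p in pairs}
    unknown = listed - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} ohnolog pair(s) not among detected paralog pairs",
            stacklevel=2,
        )
    for p in pairs:
        p.ohnolog = p.key in listed
    return pairs


def tier_members(pairs: list[ParalogPair], tier: str) -> list[ParalogPair]:
    """Pairs belonging to a tier under inclusive membership (HC ⊂ MC ⊂ LC)."""
    order = {"LC": 0, "MC": 1, "HC": 2}
    want = order[tier]
    return [p for p in pairs if order[p.tier] >= want]


def paralog_partner_map(pairs: list[ParalogPair]) -> dict[str, set[str]]:
    """Protein -> set of all its detected paralogs (most inclusive, LC, screen)."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        out.setdefault(p.protein_a, set()).add(p.protein_b)
        out.setdefault(p.protein_b, set()).add(p.protein_a)
    return out
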