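"""Two-species ground-truth scenario generator.

A scenario contains everything the pipeline consumes, with a known answer
key: a eukaryote-like species B whose paralog families were planted with
one of the four divergence fates, and a prokaryote-like species A holding
homomeric orthologs for a configurable fraction of the heteromeric B
families (singleton homomers or obligatory-homomer paralog pairs, mirroring
an ancestral homomer that duplicated and diverged into heteromers).

The generator emulates the observation process, not molecular biology:

* homology hits are summary statistics (identity/coverage sampled inside
  the confidence band of the family's intended tier, both directions);
* every true interaction is reported by all ``n_databases`` source
  databases in both bait/prey directions, and biases then corrupt the
  record stream — homomer-blind detection methods silently drop self-edge
  observations, some edges lose one bait/prey direction, false-positive
  edges appear with single-database single-direction support, and
  mislocalized false edges appear with strong support but between proteins
  of disjoint compartments;
* retrotransposon-like confounder families carry well-supported spurious
  self-edges, reproducing the obligatory-homomer inflation that motivates
  the mobile-element filter; their proteins carry the mobile-element flag
  and their pairs have no fate in the answer key;
* curated complexes realize each family's fate at tier C, CS or PDB, with
  copy numbers hidden at tier C and structural contacts emitted only at
  tier PDB.

All randomness flows from one seeded generator, and the draw sequence for
the planted truth does not depend on the bias probabilities, so sweeping a
bias while holding the seed fixed sweeps the observation process over an
identical ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import (
    FATES,
    HETERO_OTHERS,
    MIXED,
    OBLIGATORY_HETERO,
    OBLIGATORY_HOMO,
    ComplexRecord,
    DomainAnnotation,
    HomologyHit,
    ProteinRecord,
    RawPPIRecord,
    pair_key,
)

_DEFAULT_RANGES = {
    "LC": {"identity": (25.0, 100.0), "coverage": (40.0, 100.0)},
    "MC": {"identity": (30.0, 100.0), "coverage": (50.0, 100.0)},
    "HC": {"identity": (40.0, 100.0), "coverage": (60.0, 100.0)},
}


class ConfigurationError(ValueError):
    """An invalid scenario configuration; the message names the field."""


@dataclass
class ScenarioConfig:
    """Knobs of the generator; defaults give a clean mid-sized scenario.

    ``n_families_per_fate`` overrides the ``fate_mix`` apportionment of
    ``n_families`` when given.  All bias probabilities default to zero;
    each one models a distinct observation artifact (see module docstring).
    """

    seed: int = 0
    n_families: int = 200
    n_families_per_fate: dict[str, int] | None = None
    fate_mix: dict[str, float] = field(
        default_factory=lambda: {f: 0.25 for f in FATES}
    )
    n_singletons: int = 40
    n_databases: int = 7
    p_false_positive_edge: float = 0.0
    p_homomer_blind_method: float = 0.0
    p_missing_direction: float = 0.0
    n_compartments: int = 4
    p_mislocalized_edge: float = 0.0
    n_retrotransposon_families: int = 5
    retro_family_size: int = 18
    identity_coverage_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            t: {k: tuple(v) for k, v in d.items()}
            for t, d in _DEFAULT_RANGES.items()
        }
    )
    transition_fraction: float = 1 / 3
    a_singleton_fraction: float = 2 / 3
    complex_tier_mix: dict[str, float] = field(
        default_factory=lambda: {"C": 1 / 3, "CS": 1 / 3, "PDB": 1 / 3}
    )

    def validate(self) -> None:
        for name in (
            "n_families",
            "n_singletons",
            "n_retrotransposon_families",
            "retro_family_size",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_databases < 2:
            raise ConfigurationError("n_databases must be >= 2")
        if self.n_compartments < 1:
            raise ConfigurationError("n_compartments must be >= 1")
        for name in (
            "p_false_positive_edge",
            "p_homomer_blind_method",
            "p_missing_direction",
            "p_mislocalized_edge",
            "transition_fraction",
            "a_singleton_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if set(self.fate_mix) != set(FATES):
            raise ConfigurationError(
                f"fate_mix must have exactly the keys {list(FATES)}"
            )
        if any(p < 0 for p in self.fate_mix.values()):
            raise ConfigurationError("fate_mix probabilities must be >= 0")
        if abs(sum(self.fate_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("fate_mix must sum to 1 within 1e-9")
        if self.n_families_per_fate is not None:
            if set(self.n_families_per_fate) - set(FATES):
                raise ConfigurationError(
                    "n_families_per_fate contains unknown fate keys"
                )
            if any(c < 0 for c in self.n_families_per_fate.values()):
                raise ConfigurationError("n_families_per_fate counts must be >= 0")
        if set(self.identity_coverage_ranges) != {"LC", "MC", "HC"}:
            raise ConfigurationError(
                "identity_coverage_ranges must have keys LC, MC, HC"
            )
        for axis in ("identity", "coverage"):
            lo = [self.identity_coverage_ranges[t][axis][0] for t in ("LC", "MC", "HC")]
            hi = [self.identity_coverage_ranges[t][axis][1] for t in ("LC", "MC", "HC")]
            if not (lo[0] <= lo[1] <= lo[2]) or not (hi[0] >= hi[1] >= hi[2]):
                raise ConfigurationError(
                    f"identity_coverage_ranges not nested on {axis}: the HC "
                    "range must lie inside MC, and MC inside LC"
                )
        if abs(sum(self.complex_tier_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("complex_tier_mix must sum to 1 within 1e-9")

    def family_counts(self) -> dict[str, int]:
        """Families per fate: explicit counts, or largest-remainder shares."""
        if self.n_families_per_fate is not None:
            return {f: self.n_families_per_fate.get(f, 0) for f in FATES}
        exact = {f: self.fate_mix[f] * self.n_families for f in FATES}
        counts = {f: int(exact[f]) for f in FATES}
        short = self.n_families - sum(counts.values())
        by_remainder = sorted(
            FATES, key=lambda f: (-(exact[f] - counts[f]), f)
        )
        for f in by_remainder[:short]:
            counts[f] += 1
        return counts

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["identity_coverage_ranges"] = {
            t: {k: list(v) for k, v in r.items()}
            for t, r in self.identity_coverage_ranges.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "identity_coverage_ranges" in d:
            d["identity_coverage_ranges"] = {
                t: {k: tuple(v) for k, v in r.items()}
                for t, r in d["identity_coverage_ranges"].items()
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """The answer key of a scenario.

    Pair-keyed maps use canonical sorted tuples.  Retrotransposon pairs are
    deliberately absent from ``pair_fates``: their self-edges are planted
    observation artifacts, not family fates.
    """

    pair_fates: dict[tuple[str, str], str] = field(default_factory=dict)
    intended_tiers: dict[tuple[str, str], str] = field(default_factory=dict)
    self_flags: dict[str, bool] = field(default_factory=dict)
    cross_flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    hetero_partner: dict[tuple[str, str], str] = field(default_factory=dict)
    retro_proteins: set[str] = field(default_factory=set)
    a_ortholog_status: dict[tuple[str, str], str] = field(default_factory=dict)
    a_orthologs: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    a_homomers: set[str] = field(default_factory=set)
    a_homomer_pairs: list[tuple[str, str]] = field(default_factory=list)
    transition_orders: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict
    )
    complex_compositions: dict[str, dict[str, int]] = field(default_factory=dict)
    injected_false_edges: list[tuple[str, str]] = field(default_factory=list)
    injected_mislocalized_edges: list[tuple[str, str]] = field(default_factory=list)

    def check_consistency(self) -> None:
        """Fate labels must agree with the planted flag triples."""
        for (a, b), fate in self.pair_fates.items():
            s_a, s_b = self.self_flags.get(a, False), self.self_flags.get(b, False)
            cross = self.cross_flags.get((a, b), False)
            ok = {
                OBLIGATORY_HOMO: s_a and s_b and not cross,
                OBLIGATORY_HETERO: cross and not s_a and not s_b,
                MIXED: cross and (s_a or s_b),
                HETERO_OTHERS: (s_a != s_b) and not cross,
            }[fate]
            if not ok:
                raise AssertionError(
                    f"truth pair {(a, b)} labelled {fate} but flags are "
                    f"self=({s_a},{s_b}) cross={cross}"
                )


@dataclass
class Scenario:
    """A fully generated two-species dataset plus its answer key."""

    config: ScenarioConfig
    proteins: list[ProteinRecord]
    domains: list[DomainAnnotation]
    hits_a: list[HomologyHit]
    hits_b: list[HomologyHit]
    ppi_a: list[RawPPIRecord]
    ppi_b: list[RawPPIRecord]
    complexes_a: list[ComplexRecord]
    complexes_b: list[ComplexRecord]
    inter_ab: list[HomologyHit]
    inter_ba: list[HomologyHit]
    truth: GroundTruth

    @property
    def localization(self) -> dict[str, set[str]]:
        return {p.protein_id: set(p.compartments) for p in self.proteins}

    @property
    def flagged_proteins(self) -> set[str]:
        return {p.protein_id for p in self.proteins if p.mobile_element}

    @property
    def lengths(self) -> dict[str, int]:
        return {p.protein_id: p.length for p in self.proteins}


@dataclass
class _Family:
    fam_id: str
    fate: str
    a: str
    b: str
    tier: str
    identity: float
    coverage: float
    e_value: float
    compartment: str
    domain: str
    self_a: bool
    self_b: bool
    partner: str | None = None  # hetero-others gained partner
    transition: bool = False
    a_unit: tuple[str, ...] = ()
    b_order: int = 2  # oligomeric order of the heteromeric complex


def _round2_in_band(value: float, lo: float) -> float:
    v = np.floor(value * 100) / 100
    return float(max(v, lo))


def _sample_band(rng: np.random.Generator, lo: float, hi: float) -> float:
    return _round2_in_band(float(rng.uniform(lo, hi)), lo)


def _tier_bands(
    ranges: dict[str, dict[str, tuple[float, float]]], tier: str
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exclusive sampling band so a pair's best hit lands exactly in ``tier``."""
    nxt = {"LC": "MC", "MC": "HC"}.get(tier)
    bands = []
    for axis in ("identity", "coverage"):
        lo = ranges[tier][axis][0]
        hi = ranges[nxt][axis][0] - 0.01 if nxt else ranges[tier][axis][1]
        bands.append((lo, hi))
    return bands[0], bands[1]


def _log_uniform_evalue(rng: np.random.Generator, lo_exp: int, hi_exp: int) -> float:
    return float(10.0 ** -int(rng.integers(lo_exp, hi_exp)))


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full two-species scenario; byte-deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    proteins: list[ProteinRecord] = []
    domains: list[DomainAnnotation] = []
    lengths: dict[str, int] = {}

    def add_protein(pid, species, compartment, mobile=False):
        length = int(rng.integers(200, 1200))
        lengths[pid] = length
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                species=species,
                length=length,
                compartments=frozenset({compartment}),
                mobile_element=mobile,
            )
        )

    compartments = [f"comp{i + 1}" for i in range(config.n_compartments)]

    # --- plant species-B paralog families -------------------------------
    counts = config.family_counts()
    families: list[_Family] = []
    fam_no = 0
    for fate in FATES:
        for _ in range(counts[fate]):
            fam_no += 1
            fid = f"F{fam_no:04d}"
            a, b = f"Y{fam_no:04d}A", f"Y{fam_no:04d}B"
            tier = str(rng.choice(("LC", "MC", "HC")))
            (ilo, ihi), (clo, chi) = _tier_bands(
                config.identity_coverage_ranges, tier
            )
            fam = _Family(
                fam_id=fid,
                fate=fate,
                a=a,
                b=b,
                tier=tier,
                identity=_sample_band(rng, ilo, ihi),
                coverage=_sample_band(rng, clo, chi),
                e_value=_log_uniform_evalue(rng, 8, 40),
                compartment=str(rng.choice(compartments)),
                domain=f"DOM{fam_no:04d}",
                self_a=fate in (OBLIGATORY_HOMO, MIXED, HETERO_OTHERS),
                self_b=fate == OBLIGATORY_HOMO
                or (fate == MIXED and bool(rng.random() < 0.5)),
            )
            if fate == HETERO_OTHERS:
                fam.partner = f"P{fam_no:04d}"
            families.append(fam)

    for fam in families:
        add_protein(fam.a, "B", fam.compartment)
        add_protein(fam.b, "B", fam.compartment)
        domains.append(DomainAnnotation(fam.a, fam.domain, 1e-9))
        domains.append(DomainAnnotation(fam.b, fam.domain, 1e-9))
        if fam.partner:
            add_protein(fam.partner, "B", fam.compartment)
            domains.append(DomainAnnotation(fam.partner, f"DOMP{fam.fam_id[1:]}", 1e-9))
        truth.self_flags[fam.a] = fam.self_a
        truth.self_flags[fam.b] = fam.self_b
        key = pair_key(fam.a, fam.b)
        truth.pair_fates[key] = fam.fate
        truth.intended_tiers[key] = fam.tier
        truth.cross_flags[key] = fam.fate in (OBLIGATORY_HETERO, MIXED)
        if fam.partner:
            truth.hetero_partner[key] = fam.partner
            truth.self_flags[fam.partner] = False

    # --- species-B singletons (no paralogs; half of them homomers) ------
    for i in range(config.n_singletons):
        pid = f"YS{i + 1:03d}"
        add_protein(pid, "B", str(rng.choice(compartments)))
        domains.append(DomainAnnotation(pid, f"DOMS{i + 1:03d}", 1e-9))
        truth.self_flags[pid] = bool(rng.random() < 0.5)

    # --- retrotransposon-like confounder families -----------------------
    retro_families: list[list[str]] = []
    for j in range(config.n_retrotransposon_families):
        comp = str(rng.choice(compartments))
        members = [
            f"RT{j + 1:02d}_{k + 1:02d}" for k in range(config.retro_family_size)
        ]
        for pid in members:
            add_protein(pid, "B", comp, mobile=True)
            domains.append(DomainAnnotation(pid, f"DOMRT{j + 1:02d}", 1e-9))
            truth.retro_proteins.add(pid)
            truth.self_flags[pid] = True
        retro_families.append(members)

    # --- select homomer-to-heteromer transition families ----------------
    het_fams = [f for f in families if f.fate in (OBLIGATORY_HETERO, MIXED)]
    n_transitions = int(round(config.transition_fraction * len(het_fams)))
    chosen = sorted(
        rng.choice(len(het_fams), size=n_transitions, replace=False).tolist()
    ) if n_transitions else []
    for idx in chosen:
        fam = het_fams[idx]
        fam.transition = True
        singleton = bool(rng.random() < config.a_singleton_fraction)
        tag = fam.fam_id[1:]
        fam.a_unit = (f"E{tag}",) if singleton else (f"E{tag}A", f"E{tag}B")
        fam.b_order = 2 if rng.random() < 0.5 else 4
        key = pair_key(fam.a, fam.b)
        truth.a_ortholog_status[key] = "singleton" if singleton else "pair"
        truth.a_orthologs[key] = fam.a_unit
        truth.transition_orders[key] = (2, fam.b_order)
    for fam in het_fams:
        if not fam.transition:
            truth.a_ortholog_status[pair_key(fam.a, fam.b)] = "absent"

    for fam in families:
        if not fam.transition:
            continue
        comp = str(rng.choice(compartments))
        for pid in fam.a_unit:
            add_protein(pid, "A", comp)
            domains.append(DomainAnnotation(pid, fam.domain, 1e-9))
            truth.a_homomers.add(pid)
            truth.self_flags[pid] = True
        if len(fam.a_unit) == 2:
            truth.a_homomer_pairs.append(pair_key(*fam.a_unit))

    # --- intra-species homology hits ------------------------------------
    def mk_hits(q, s, ident, cov, evalue):
        out = []
        for qq, ss in ((q, s), (s, q)):
            qlen = lengths[qq]
            aln = max(1, int(round(cov / 100.0 * qlen)))
            out.append(
                HomologyHit(
                    query_id=qq,
                    subject_id=ss,
                    percent_identity=ident,
                    query_coverage=cov,
                    e_value=evalue,
                    alignment_length=aln,
                )
            )
        return out

    hits_b: list[HomologyHit] = []
    for fam in families:
        hits_b.extend(mk_hits(fam.a, fam.b, fam.identity, fam.coverage, fam.e_value))
    for members in retro_families:
        for i, p in enumerate(members):
            for q in members[i + 1 :]:
                ident = _sample_band(rng, 85.0, 99.0)
                cov = _sample_band(rng, 90.0, 100.0)
                hits_b.extend(
                    mk_hits(p, q, ident, cov, _log_uniform_evalue(rng, 30, 80))
                )

    hits_a: list[HomologyHit] = []
    for fam in families:
        if len(fam.a_unit) == 2:
            ident = _sample_band(rng, 40.0, 90.0)
            cov = _sample_band(rng, 60.0, 100.0)
            hits_a.extend(
                mk_hits(*fam.a_unit, ident, cov, _log_uniform_evalue(rng, 10, 60))
            )

    # --- inter-species reciprocal hits for transition families ----------
    inter_ab: list[HomologyHit] = []
    inter_ba: list[HomologyHit] = []
    for fam in families:
        if not fam.transition:
            continue
        for a_prot in fam.a_unit:
            for b_prot in (fam.a, fam.b):
                ident = _sample_band(rng, 28.0, 60.0)
                cov = _sample_band(rng, 50.0, 95.0)
                ev = _log_uniform_evalue(rng, 6, 40)
                qlen_a, qlen_b = lengths[a_prot], lengths[b_prot]
                inter_ab.append(
                    HomologyHit(a_prot, b_prot, ident, cov, ev,
                                max(1, int(round(cov / 100.0 * qlen_a))))
                )
                inter_ba.append(
                    HomologyHit(b_prot, a_prot, ident, cov, ev,
                                max(1, int(round(cov / 100.0 * qlen_b))))
                )

    # --- raw PPI records -------------------------------------------------
    db_names = [f"db{i + 1}" for i in range(config.n_databases)]

    def emit_true_edge(records, x, y):
        """All-database, both-direction reporting, corrupted by the biases."""
        if x == y:
            for i, db in enumerate(db_names):
                if rng.random() < config.p_homomer_blind_method:
                    continue  # observation made by a homomer-blind method
                records.append(
                    RawPPIRecord(x, x, db, bait_id=x, prey_id=x,
                                 method_class=_method(i))
                )
        else:
            one_direction = rng.random() < config.p_missing_direction
            for i, db in enumerate(db_names):
                records.append(
                    RawPPIRecord(x, y, db, bait_id=x, prey_id=y,
                                 method_class=_method(i))
                )
                if not one_direction:
                    records.append(
                        RawPPIRecord(x, y, db, bait_id=y, prey_id=x,
                                     method_class=_method(i))
                    )

    def _method(i: int) -> str:
        return "two_hybrid" if i % 2 == 0 else "pulldown"

    true_self = sorted(p for p, flag in truth.self_flags.items() if flag)
    true_cross = sorted(k for k, flag in truth.cross_flags.items() if flag)
    partner_edges = sorted(
        (pair_key(truth.hetero_partner[k], k[0] if not truth.self_flags[k[0]] else k[1]))
        for k in truth.hetero_partner
    )
    true_edge_keys = (
        {(p, p) for p in true_self} | set(true_cross) | set(partner_edges)
    )

    ppi_a: list[RawPPIRecord] = []
    ppi_b: list[RawPPIRecord] = []
    species_of = {p.protein_id: p.species for p in proteins}
    for p in true_self:
        emit_true_edge(ppi_a if species_of[p] == "A" else ppi_b, p, p)
    for (x, y) in true_cross:
        emit_true_edge(ppi_b, x, y)
    for (x, y) in partner_edges:
        emit_true_edge(ppi_b, x, y)

    # Noise injections (species B only, where the filters act).
    b_proteins = sorted(p.protein_id for p in proteins if p.species == "B")
    comp_of = {p.protein_id: next(iter(p.compartments)) for p in proteins}
    injected: set[tuple[str, str]] = set()
    for p in b_proteins:
        if rng.random() < config.p_false_positive_edge:
            q = b_proteins[int(rng.integers(len(b_proteins)))]
            key = pair_key(p, q)
            if q != p and key not in true_edge_keys and key not in injected:
                injected.add(key)
                truth.injected_false_edges.append(key)
                db = db_names[int(rng.integers(len(db_names)))]
                ppi_b.append(
                    RawPPIRecord(key[0], key[1], db, bait_id=key[0],
                                 prey_id=key[1], method_class="two_hybrid")
                )
    for p in b_proteins:
        if rng.random() < config.p_mislocalized_edge:
            others = [q for q in b_proteins if comp_of[q] != comp_of[p]]
            if not others:
                continue
            q = others[int(rng.integers(len(others)))]
            key = pair_key(p, q)
            if key in true_edge_keys or key in injected:
                continue
            injected.add(key)
            truth.injected_mislocalized_edges.append(key)
            for db in db_names[:2]:
                for bait, prey in ((key[0], key[1]), (key[1], key[0])):
                    ppi_b.append(
                        RawPPIRecord(key[0], key[1], db, bait_id=bait,
                                     prey_id=prey, method_class="pulldown")
                    )

    # --- curated complexes ----------------------------------------------
    tier_names = sorted(config.complex_tier_mix)
    tier_probs = [config.complex_tier_mix[t] for t in tier_names]

    def sample_tier(known_stoich_only: bool = False) -> str:
        t = str(rng.choice(tier_names, p=tier_probs))
        if known_stoich_only and t == "C":
            t = "CS" if rng.random() < 0.5 else "PDB"
        return t

    complexes_a: list[ComplexRecord] = []
    complexes_b: list[ComplexRecord] = []
    cx_no = 0

    def add_complex(dest, members: dict[str, int], tier: str,
                    contacts: list[tuple[str, str]]):
        nonlocal cx_no
        cx_no += 1
        cid = f"CPX{cx_no:05d}"
        truth.complex_compositions[cid] = dict(members)
        dest.append(
            ComplexRecord(
                complex_id=cid,
                tier=tier,
                members=(
                    {m: None for m in members} if tier == "C" else dict(members)
                ),
                contacts=contacts if tier == "PDB" else [],
            )
        )

    for fam in families:
        if fam.fate == OBLIGATORY_HOMO:
            for p in (fam.a, fam.b):
                tier = sample_tier()
                add_complex(complexes_b, {p: 2}, tier, [(p, p)])
        elif fam.fate == OBLIGATORY_HETERO:
            tier = sample_tier(known_stoich_only=fam.transition)
            s = fam.b_order // 2
            add_complex(
                complexes_b, {fam.a: s, fam.b: s}, tier, [(fam.a, fam.b)]
            )
        elif fam.fate == MIXED:
            tier = sample_tier(known_stoich_only=fam.transition)
            s = fam.b_order // 2
            add_complex(
                complexes_b, {fam.a: s, fam.b: s}, tier, [(fam.a, fam.b)]
            )
            if fam.self_a:
                add_complex(complexes_b, {fam.a: 2}, sample_tier(), [(fam.a, fam.a)])
            if fam.self_b:
                add_complex(complexes_b, {fam.b: 2}, sample_tier(), [(fam.b, fam.b)])
        elif fam.fate == HETERO_OTHERS:
            add_complex(complexes_b, {fam.a: 2}, sample_tier(), [(fam.a, fam.a)])
            add_complex(
                complexes_b, {fam.b: 1, fam.partner: 1}, sample_tier(),
                [(fam.b, fam.partner)],
            )
        if fam.transition:
            for p in fam.a_unit:
                tier = sample_tier(known_stoich_only=True)
                add_complex(complexes_a, {p: 2}, tier, [(p, p)])

    truth.check_consistency()
    truth.a_homomer_pairs.sort()
    truth.injected_false_edges.sort()
    truth.injected_mislocalized_edges.sort()
    proteins.sort(key=lambda p: p.protein_id)
    domains.sort(key=lambda d: (d.protein_id, d.domain_id))
    return Scenario(
        config=config,
        proteins=proteins,
        domains=domains,
        hits_a=hits_a,
        hits_b=hits_b,
        ppi_a=ppi_a,
        ppi_b=ppi_b,
        complexes_a=complexes_a,
        complexes_b=complexes_b,
        inter_ab=inter_ab,
        inter_ba=inter_ba,
        truth=truth,
    )


# --------------------------------------------------------------------------
# On-disk representation: the exact TSV/JSON dialects the pipeline reads.
# --------------------------------------------------------------------------

def _blast6_rows(hits: list[HomologyHit], lengths: dict[str, int]) -> list[str]:
    rows = []
    for h in hits:
        qlen = lengths[h.query_id]
        aln = h.alignment_length
        mismatch = int(round(aln * (1 - h.percent_identity / 100.0)))
        bitscore = round(aln * 2.0, 1)
        rows.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.2f}",
                    str(aln),
                    str(mismatch),
                    "0",
                    "1",
                    str(min(aln, qlen)),
                    "1",
                    str(aln),
                    repr(h.e_value),
                    f"{bitscore:.1f}",
                    f"{h.query_coverage:.2f}",
                ]
            )
        )
    return rows


def _pk(key: tuple[str, str]) -> str:
    return f"{key[0]}|{key[1]}"


def _unpk(s: str) -> tuple[str, str]:
    a, b = s.split("|")
    return (a, b)


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "pair_fates": {_pk(k): v for k, v in sorted(truth.pair_fates.items())},
        "intended_tiers": {
            _pk(k): v for k, v in sorted(truth.intended_tiers.items())
        },
        "self_flags": dict(sorted(truth.self_flags.items())),
        "cross_flags": {_pk(k): v for k, v in sorted(truth.cross_flags.items())},
        "hetero_partner": {
            _pk(k): v for k, v in sorted(truth.hetero_partner.items())
        },
        "retro_proteins": sorted(truth.retro_proteins),
        "a_ortholog_status": {
            _pk(k): v for k, v in sorted(truth.a_ortholog_status.items())
        },
        "a_orthologs": {
            _pk(k): list(v) for k, v in sorted(truth.a_orthologs.items())
        },
        "a_homomers": sorted(truth.a_homomers),
        "a_homomer_pairs": [list(k) for k in sorted(truth.a_homomer_pairs)],
        "transition_orders": {
            _pk(k): list(v) for k, v in sorted(truth.transition_orders.items())
        },
        "complex_compositions": {
            k: v for k, v in sorted(truth.complex_compositions.items())
        },
        "injected_false_edges": [
            list(k) for k in sorted(truth.injected_false_edges)
        ],
        "injected_mislocalized_edges": [
            list(k) for k in sorted(truth.injected_mislocalized_edges)
        ],
    }


def _truth_from_json(d: dict) -> GroundTruth:
    return GroundTruth(
        pair_fates={_unpk(k): v for k, v in d["pair_fates"].items()},
        intended_tiers={_unpk(k): v for k, v in d["intended_tiers"].items()},
        self_flags=dict(d["self_flags"]),
        cross_flags={_unpk(k): v for k, v in d["cross_flags"].items()},
        hetero_partner={_unpk(k): v for k, v in d["hetero_partner"].items()},
        retro_proteins=set(d["retro_proteins"]),
        a_ortholog_status={
            _unpk(k): v for k, v in d["a_ortholog_status"].items()
        },
        a_orthologs={
            _unpk(k): tuple(v) for k, v in d["a_orthologs"].items()
        },
        a_homomers=set(d["a_homomers"]),
        a_homomer_pairs=[tuple(k) for k in d["a_homomer_pairs"]],
        transition_orders={
            _unpk(k): tuple(v) for k, v in d["transition_orders"].items()
        },
        complex_compositions=d["complex_compositions"],
        injected_false_edges=[tuple(k) for k in d["injected_false_edges"]],
        injected_mislocalized_edges=[
            tuple(k) for k in d["injected_mislocalized_edges"]
        ],
    )


def _complexes_to_json(complexes: list[ComplexRecord]) -> list[dict]:
    return [
        {
            "complex_id": cx.complex_id,
            "tier": cx.tier,
            "members": [
                {"id": m, "copies": c} for m, c in sorted(cx.members.items())
            ],
            "contacts": [list(c) for c in sorted(cx.contacts)],
        }
        for cx in sorted(complexes, key=lambda c: c.complex_id)
    ]


def complexes_from_json(items: list[dict]) -> list[ComplexRecord]:
    return [
        ComplexRecord(
            complex_id=d["complex_id"],
            tier=d["tier"],
            members={m["id"]: m["copies"] for m in d["members"]},
            contacts=[tuple(c) for c in d.get("contacts", [])],
        )
        for d in items
    ]


def write_scenario(dir_path, scenario: Scenario) -> list[Path]:
    """Write every scenario file in the dialects the pipeline readers consume.

    Emits proteins.tsv, localization.tsv, domains.tsv, per-species blast6
    hit tables and raw PPI TSVs, complexes.json, inter-species fwd/rev
    blast6 tables, truth.json and config.yaml.  Deterministic: the same
    scenario always produces byte-identical files.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    lengths = scenario.lengths
    written = []

    def emit(name: str, text: str):
        path = out / name
        path.write_text(text)
        written.append(path)

    rows = ["protein_id\tspecies\tlength\tmobile_element\tcompartments"]
    for p in sorted(scenario.proteins, key=lambda x: x.protein_id):
        rows.append(
            f"{p.protein_id}\t{p.species}\t{p.length}\t"
            f"{int(p.mobile_element)}\t{';'.join(sorted(p.compartments))}"
        )
    emit("proteins.tsv", "\n".join(rows) + "\n")

    rows = ["protein_id\tcompartment"]
    for p in sorted(scenario.proteins, key=lambda x: x.protein_id):
        for c in sorted(p.compartments):
            rows.append(f"{p.protein_id}\t{c}")
    emit("localization.tsv", "\n".join(rows) + "\n")

    rows = ["protein_id\tdomain_id\tp_value"]
    for d in sorted(scenario.domains, key=lambda x: (x.protein_id, x.domain_id)):
        rows.append(f"{d.protein_id}\t{d.domain_id}\t{d.p_value!r}")
    emit("domains.tsv", "\n".join(rows) + "\n")

    for name, hits in (
        ("hits_a.blast6.tsv", scenario.hits_a),
        ("hits_b.blast6.tsv", scenario.hits_b),
        ("interspecies_ab.blast6.tsv", scenario.inter_ab),
        ("interspecies_ba.blast6.tsv", scenario.inter_ba),
    ):
        emit(name, "".join(r + "\n" for r in _blast6_rows(hits, lengths)))

    header = (
        "interactor_a\tinteractor_b\tsource_db\tbait_id\tprey_id\t"
        "method_class\tevidence_class"
    )
    for name, records in (("ppi_a.tsv", scenario.ppi_a), ("ppi_b.tsv", scenario.ppi_b)):
        rows = [header]
        for r in records:
            rows.append(
                f"{r.interactor_a}\t{r.interactor_b}\t{r.source_db}\t"
                f"{r.bait_id or ''}\t{r.prey_id or ''}\t{r.method_class}\t"
                f"{r.evidence_class}"
            )
        emit(name, "\n".join(rows) + "\n")

    emit(
        "complexes.json",
        json.dumps(
            {
                "A": _complexes_to_json(scenario.complexes_a),
                "B": _complexes_to_json(scenario.complexes_b),
            },
            indent=1,
        )
        + "\n",
    )
    emit("truth.json", json.dumps(_truth_to_json(scenario.truth), indent=1) + "\n")
    emit(
        "config.yaml",
        yaml.safe_dump(scenario.config.to_dict(), sort_keys=True),
    )
    return written


def read_scenario(dir_path) -> Scenario:
    """Read back a scenario directory written by :func:`write_scenario`."""
    from .io import read_domains, read_ppi, read_proteins
    from .paralogs import read_blast6

    src = Path(dir_path)
    config = ScenarioConfig.from_dict(
        yaml.safe_load((src / "config.yaml").read_text())
    )
    proteins = read_proteins(src / "proteins.tsv")
    lengths = {p.protein_id: p.length for p in proteins}
    with open(src / "complexes.json") as fh:
        cx = json.load(fh)
    with open(src / "truth.json") as fh:
        truth = _truth_from_json(json.load(fh))
    return Scenario(
        config=config,
        proteins=proteins,
        domains=read_domains(src / "domains.tsv"),
        hits_a=read_blast6(src / "hits_a.blast6.tsv", lengths),
        hits_b=read_blast6(src / "hits_b.blast6.tsv", lengths),
        ppi_a=read_ppi(src / "ppi_a.tsv"),
        ppi_b=read_ppi(src / "ppi_b.tsv"),
        complexes_a=complexes_from_json(cx["A"]),
        complexes_b=complexes_from_json(cx["B"]),
        inter_ab=read_blast6(src / "interspecies_ab.blast6.tsv", lengths),
        inter_ba=read_blast6(src / "interspecies_ba.blast6.tsv", lengths),
        truth=truth,
    )
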