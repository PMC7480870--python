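# Methods

## The classification model

A paralogous pair's divergence fate is a deterministic function of five
booleans derived from one interaction dataset: `self_a`, `self_b` (each
paralog forms a homomer), `cross` (the paralogs interact with each other),
and `other_partner_a/b` (the paralog interacts with a protein that is
neither itself nor any of its detected paralogs). The mapping:

* `cross ∧ ¬self_a ∧ ¬self_b` → obligatory heteromer
* `cross ∧ (self_a ∨ self_b)` → mixed homo/heteromer
* `¬cross ∧ self_a ∧ self_b` → obligatory homomer (stringent)
* `¬cross ∧ exactly one self ∧ other partner on the non-self paralog` →
  hetero-others (stringent only)
* flexible criterion: every `¬cross ∧ (≥1 self)` case → obligatory
  homomer; hetero-others is never emitted
* anything else → unassigned

Pairs where neither paralog shows any interaction are intractable from
interaction data alone (they may be monomers or simply unobserved) and map
to `unassigned`; unassigned pairs are excluded from all fate-fraction
denominators. The flexible criterion absorbs one-self/no-partner cases
into obligatory homomer as well — the natural completion of "at least one
self-interacts, no cross-interaction".

The hetero-others rule requires the gained partner on the paralog that
*lost* the homomer; a pair whose self-interacting member has outside
partners but whose non-self member has none stays unassigned under the
stringent criterion. "Non-paralogous partner" is judged against the
analysis-wide paralogy map at the most inclusive (LC) tier, the most
conservative screen for calling a partner genuinely new.

## Paralog tiers

Tiers are inclusive (HC ⊂ MC ⊂ LC) with inclusive (≥) thresholds:
LC 25%/40%, MC 30%/50%, HC 40%/60% identity/query-coverage, HC adding
identical domain content. Query coverage is the aligned fraction of the
query sequence; a pair passes a tier if at least one direction's best hit
meets both thresholds (the permissive reading; the generator emits
symmetric hits so synthetic tests are unambiguous). When multiple HSPs
exist per pair only the minimum-e-value hit is used — HSPs are not tiled —
with ties broken by identity, then coverage, then query id, so collapsing
is deterministic under input permutation.

Domain content is compared as a *multiset* of significant domain
identifiers (assignment p < 1e-5): copy-number differences deny HC. Two
proteins with no significant domains have equal (empty) content. Manual
curation of putative paralogs is represented by an optional exclusion
list; ohnolog annotation is a pure flag with no effect on tiering.

## PPI evidence model and filters

Records are aggregated per unordered pair; databases, bait/prey directions
and method classes are unioned. Only experimentally observed records
participate (predicted and text-mining entries are dropped at compilation).
Database support is counted on database *names* — curation overlap between
databases is expected and accepted, the two-database demand being a guard
against annotation error, not a claim of independent observation.

Filter 2's bait-and-prey condition is unsatisfiable for a self-edge (one
protein cannot occupy two roles), so self-edges are retained on the
two-database condition alone; filter 3 never removes self-edges. A protein
with no localization data is treated as compatible with every compartment:
only demonstrated cross-compartment pairs are excluded, since penalizing
missing annotation would bias against heteromers. Localization labels are
lowercased before exact matching; a synonym map can be supplied where
vocabularies differ.

The `subset_non_baitprey_methods` view keeps pairs *all* of whose records
come from methods other than two-hybrid/pull-down, then applies the
database-count and co-localization filters but not the direction filter
(which such methods cannot satisfy); it exists to check that the direction
demand does not distort the fate distribution.

## Curated-complex evidence

Three tiers with increasing information: C (composition only), CS
(composition + stoichiometry), PDB (+ structural inter-subunit contacts).
Homomer calls: PDB needs copy number ≥2 plus a self-contact; CS needs copy
number ≥2 plus a PPI self-edge; C needs membership plus a PPI self-edge,
with an explicitly known copy number <2 ruling that complex out (known
copy numbers are honored, unknown ones fall back on the self-edge).
Cross calls: a PDB contact between the paralogs, or co-membership plus a
PPI cross-edge at CS/C. A would-be obligatory homomer that cross-interacts
in the filtered PPI network is vetoed to unassigned rather than silently
relabeled. Self- and cross-evidence are always read from the same PPI
filter level being evaluated, so grid cells remain comparable.

Complex counting is by unique complex id per fate; a complex containing
pairs of k fates contributes to k cells. Cross-interacting fates require
both pair members in the complex; homomer-side fates count complexes
containing either member, since each paralog's own homomeric complex is
the object of interest (two homomers of one obligatory-homo pair are two
complexes).

## Cross-species transitions

Orthology links require sub-threshold hits (e < 1e-5) in *both* reciprocal
searches; strict best-hit reciprocity is available behind a flag but is
not the default, the weaker mutual-hit reading being tunable rather than
hard-coded. Links are then restricted to protein pairs sharing ≥1
significant domain; an optional accept-list stands in for manual
same-function checking. A transition record joins a homomeric ancestral
unit (singleton, or a paralogous pair grouped as one unit) to a heteromeric
(obligatory-hetero or mixed) derived pair; by default one linked member of
the derived pair suffices, since divergent paralogs can lose detectable
similarity asymmetrically, with a both-members flag for the strict variant.
Oligomeric order is the total subunit count of a stoichiometry-known
(CS/PDB) complex; order relations are `retained`/`changed` only when both
orders are known, else `unknown`.

## The synthetic generator

The generator plants families with known fates and emulates the
observation process. Defaults: 200 families split evenly over the four
fates (no empirical pre-filter fate frequencies are established for real
proteomes, so the mix is a free, uniform prior), 40 singleton proteins,
7 source databases, 4 compartments, and 5 retrotransposon-like families of
18 proteins (90 flagged proteins) mirroring the scale of the long-terminal-
repeat confounder families observed in yeast PPI data. A third of
heteromeric families receive a homomeric ortholog in the prokaryote-like
species, two thirds of those singletons — the proportions reported for the
yeast/E. coli comparison. Identity/coverage are sampled uniformly inside
the intended tier's exclusive band with closed lower boundaries (tier
thresholds are inclusive).

Every true interaction is reported by all databases in both directions;
biases then corrupt records independently: homomer-blind method draws
suppress self-edge observations, a missing-direction draw collapses an
edge to one bait/prey direction (removed by filter 2), false-positive
edges get single-database single-direction support (removed by filter 2),
and mislocalized edges get strong support but disjoint compartments
(removed by filter 3). Injected artifacts never coincide with true edges,
so filter-recovery checks are exact. The draw sequence for the planted
truth precedes and is independent of the bias draws, so sweeping a bias
probability at a fixed seed sweeps the observation process over an
identical truth.

What the generator does **not** emulate: real sequences (identity/coverage
are summary statistics, not alignments), binding affinities or
concentration-dependent homo/hetero equilibria, study bias (all true edges
are observed equally often), inter-family interaction promiscuity, and
multi-protein complexes beyond the planted dimers/tetramers. Passing the
zero-noise and bias-sweep suites therefore demonstrates correctness of the
inference rules under the stated observation model, not performance on
real proteome-scale data, where noise is structured and coverage uneven.

## Numerical and procedural choices

* All pair keys are canonical sorted tuples; writers sort all outputs, so
  identical inputs give byte-identical files.
* The retrotransposon pairs carry no fate in the answer key: their
  self-edges are planted observation artifacts. They dominate the raw
  level (~84% apparent obligatory homomers in the default scenario) and
  vanish at filter 1 (25%, the planted fraction) — the designed
  demonstration of the confounder.
* Scenario sizes in the test and acceptance runs (200-family scenarios,
  10–20 seeds per property) keep every suite in the seconds-to-a-minute
  range while leaving binomial noise far below the tested effect sizes.
* Largest-remainder apportionment converts `fate_mix` into deterministic
  family counts, so the planted truth depends only on the configuration,
  not on an extra sampling step.

## Known limitations

* The co-localization filter assumes a shared vocabulary after
  lowercasing; real multi-source localization data needs a curated synonym
  map.
* Curated mode reads PPI cross-checks from whichever edge set is passed;
  with no PPI data at all, CS- and C-tier evidence yields no calls (PDB
  tier still works), which matches the evidence model but limits
  curated-only analyses.
* The many-to-many ancestral mapping is preserved as the full bipartite
  record set; no attempt is made to collapse it into per-species counts,
  which would require a de-duplication convention the data does not
  dictate.
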