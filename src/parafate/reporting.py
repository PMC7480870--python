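"""Stringency grid assembly and full-pipeline orchestration.

The stringency grid is the package's central summary: for every cell of
(dataset x paralog tier x filter level x criterion) it tabulates how many
pairs fall into each divergence fate, with percentages computed over
assigned pairs only.  Tier membership is inclusive — an HC pair is counted
in the HC, MC and LC cells — so totals respect HC <= MC <= LC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as pio
from .complexes import (
    complex_order,
    count_complexes_by_fate,
    count_paralog_membership,
)
from .fates import build_homomer_set, classify_pairs
from .orthologs import (
    compare_orders,
    map_transitions,
    reciprocal_links,
    shared_domain_filter,
)
from .paralogs import assign_tiers, collapse_to_pairs, read_blast6
from .ppi import apply_filters, compile_edges, extract_paralog_edges
from .types import FATES, UNASSIGNED, FateAssignment

_TIER_RANK = {"LC": 0, "MC": 1, "HC": 2}


@dataclass
class StringencyGrid:
    """Long-format grid: one row per (dataset, tier, filter level, criterion)."""

    table: pd.DataFrame

    def cell(self, dataset: str, tier: str, filter_level: str, criterion: str):
        t = self.table
        rows = t[
            (t.dataset == dataset)
            & (t.tier == tier)
            & (t.filter_level == filter_level)
            & (t.criterion == criterion)
        ]
        if rows.empty:
            raise KeyError((dataset, tier, filter_level, criterion))
        return rows.iloc[0]


def build_grid(assignments: list[FateAssignment]) -> StringencyGrid:
    """Tabulate fate counts and percentages over every stringency cell.

    Raises ``ValueError`` when the assignments do not cover the full
    Cartesian product of the (dataset, filter level, criterion) axes they
    mention, or when they are empty.
    """
    if not assignments:
        raise ValueError("no assignments: cannot build a stringency grid")
    datasets = sorted({a.dataset for a in assignments})
    levels = sorted(
        {a.filter_level for a in assignments},
        key=lambda x: (["raw", "f1", "f2", "f3"].index(x) if x in ("raw", "f1", "f2", "f3") else 99, x),
    )
    criteria = sorted({a.criterion for a in assignments})
    present = {(a.dataset, a.filter_level, a.criterion) for a in assignments}
    missing = [
        (d, l, c)
        for d in datasets
        for l in levels
        for c in criteria
        if (d, l, c) not in present
    ]
    if missing:
        raise ValueError(f"incomplete stringency axes; missing combinations: {missing}")

    rows = []
    for dataset in datasets:
        for tier in ("LC", "MC", "HC"):
            for level in levels:
                for criterion in criteria:
                    cell = [
                        a
                        for a in assignments
                        if a.dataset == dataset
                        and a.filter_level == level
                        and a.criterion == criterion
                        and _TIER_RANK[a.tier] >= _TIER_RANK[tier]
                    ]
                    counts = {f: 0 for f in FATES}
                    n_unassigned = 0
                    for a in cell:
                        if a.fate == UNASSIGNED:
                            n_unassigned += 1
                        else:
                            counts[a.fate] += 1
                    total = sum(counts.values())
                    row = {
                        "dataset": dataset,
                        "tier": tier,
                        "filter_level": level,
                        "criterion": criterion,
                        "total_classified": total,
                        "n_unassigned": n_unassigned,
                        "empty_cell": total == 0,
                    }
                    for f in FATES:
                        row[f"n_{f}"] = counts[f]
                        row[f"pct_{f}"] = (
                            100.0 * counts[f] / total if total else float("nan")
                        )
                    rows.append(row)
    return StringencyGrid(pd.DataFrame(rows))


def _known_order_for(proteins: tuple[str, ...] | tuple[str, str], complexes,
                     require_all: bool = False) -> int | None:
    """Oligomeric order from the first CS/PDB complex containing the protein(s)."""
    for cx in sorted(complexes, key=lambda c: c.complex_id):
        if cx.tier == "C":
            continue
        if require_all:
            hit = all(p in cx.members for p in proteins)
        else:
            hit = any(p in cx.members for p in proteins)
        if hit:
            order = complex_order(cx)
            if order is not None:
                return order
    return None


def run_pipeline(
    scenario_dir,
    out_dir,
    strict_best_hit: bool = False,
    seed: int | None = None,
) -> dict:
    """Run every stage on a scenario directory; returns the run summary.

    Stages: paralog detection (both species) -> PPI compilation and
    filtering -> fate assignment (PPI and curated, both criteria, all
    filter levels) -> complex counting -> homomer-to-heteromer transition
    mapping -> stringency grid.  All outputs are written to ``out_dir``
    together with a JSON manifest and per-stage record counts.
    """
    from .synthetic import read_scenario

    src = Path(scenario_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = read_scenario(src)
    log: list[str] = []
    counts: dict[str, int] = {}

    def stage(name: str, n: int):
        counts[name] = n
        log.append(f"{name}: {n}")

    # Species B: paralogs, edges, fates.
    pairs_b = assign_tiers(collapse_to_pairs(scenario.hits_b), scenario.domains)
    stage("pairs_b", len(pairs_b))
    pio.write_pairs_tsv(out / "pairs_b.tsv", pairs_b)

    edges_b = extract_paralog_edges(compile_edges(scenario.ppi_b), pairs_b)
    stage("edges_b_raw", len(edges_b))
    levels_b = apply_filters(
        edges_b,
        flagged_proteins=scenario.flagged_proteins,
        localization=scenario.localization,
    )
    for level, edges in levels_b.items():
        stage(f"edges_b_{level}", len(edges))
        pio.write_edges_tsv(out / f"edges_b_{level}.tsv", edges)

    assignments_b = classify_pairs(pairs_b, levels_b, scenario.complexes_b)
    stage("assignments_b", len(assignments_b))
    pio.write_fates_tsv(out / "fates_b.tsv", assignments_b)

    grid = build_grid(assignments_b)
    grid.table.to_csv(out / "grid_b.tsv", sep="\t", index=False)

    # Curated-complex counting at the final filter level, stringent criterion.
    curated_final = [
        a
        for a in assignments_b
        if a.dataset == "curated"
        and a.filter_level == "f3"
        and a.criterion == "stringent"
    ]
    fate_counts = count_complexes_by_fate(scenario.complexes_b, curated_final)
    fate_counts["complexes_with_paralogs"] = count_paralog_membership(
        scenario.complexes_b, pairs_b
    )
    pd.Series(fate_counts).rename_axis("fate").to_frame("n_complexes").to_csv(
        out / "complex_counts_b.tsv", sep="\t"
    )

    # Species A: paralogs, edges, homomer set.
    pairs_a = assign_tiers(collapse_to_pairs(scenario.hits_a), scenario.domains)
    stage("pairs_a", len(pairs_a))
    edges_a = compile_edges(scenario.ppi_a)
    levels_a = apply_filters(edges_a)
    stage("edges_a_filtered", len(levels_a["f3"]))
    homomers_a = build_homomer_set(levels_a["f3"], scenario.complexes_a)
    stage("homomers_a", len(homomers_a))

    # Cross-species transitions: stringent criterion, final filter level.
    links = reciprocal_links(
        scenario.inter_ab, scenario.inter_ba, strict_best_hit=strict_best_hit
    )
    stage("reciprocal_links", len(links))
    links = shared_domain_filter(links, scenario.domains, scenario.domains)
    stage("domain_filtered_links", len(links))
    b_stringent = [
        a
        for a in assignments_b
        if a.dataset == "ppi" and a.filter_level == "f3" and a.criterion == "stringent"
    ]
    transitions = map_transitions(links, homomers_a, pairs_a, b_stringent)
    for record in transitions:
        compare_orders(
            record,
            _known_order_for(record.a_ids, scenario.complexes_a),
            _known_order_for(record.b_pair, scenario.complexes_b, require_all=True),
        )
    stage("transitions", len(transitions))
    pio.write_transitions_tsv(out / "transitions.tsv", transitions)

    manifest = {
        "scenario_dir": str(src),
        "strict_best_hit": strict_best_hit,
        "seed": seed if seed is not None else scenario.config.seed,
        "stage_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return {
        "pairs_b": pairs_b,
        "levels_b": levels_b,
        "assignments_b": assignments_b,
        "grid": grid,
        "complex_fate_counts": fate_counts,
        "pairs_a": pairs_a,
        "homomers_a": homomers_a,
        "transitions": transitions,
        "stage_counts": counts,
    }
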