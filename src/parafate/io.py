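"""Readers and writers for the pipeline's tabular interchange files.

All tables are plain TSV with a header row; complexes travel as JSON.
Writers sort deterministically so reruns produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .types import (
    ComplexRecord,
    DomainAnnotation,
    EvidenceEdge,
    FateAssignment,
    ParalogPair,
    ProteinRecord,
    RawPPIRecord,
)


def _read_rows(path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def read_proteins(path) -> list[ProteinRecord]:
    out = []
    for row in _read_rows(path):
        comp = row.get("compartments", "")
        out.append(
            ProteinRecord(
                protein_id=row["protein_id"],
                species=row.get("species", ""),
                length=int(row.get("length", 0) or 0),
                compartments=frozenset(c for c in comp.split(";") if c),
                mobile_element=bool(int(row.get("mobile_element", 0) or 0)),
            )
        )
    return out


def read_domains(path) -> list[DomainAnnotation]:
    return [
        DomainAnnotation(
            protein_id=row["protein_id"],
            domain_id=row["domain_id"],
            p_value=float(row["p_value"]),
        )
        for row in _read_rows(path)
    ]


def read_localization(path) -> dict[str, set[str]]:
    table: dict[str, set[str]] = {}
    for row in _read_rows(path):
        table.setdefault(row["protein_id"], set()).add(
            row["compartment"].strip().lower()
        )
    return table


def read_ppi(path) -> list[RawPPIRecord]:
    out = []
    for row in _read_rows(path):
        out.append(
            RawPPIRecord(
                interactor_a=row["interactor_a"],
                interactor_b=row["interactor_b"],
                source_db=row["source_db"],
                bait_id=row.get("bait_id") or None,
                prey_id=row.get("prey_id") or None,
                method_class=row.get("method_class") or "other",
                evidence_class=row.get("evidence_class") or "experimental",
            )
        )
    return out


def read_complexes(path) -> list[ComplexRecord]:
    """Read complexes.json; accepts a flat list or a species-keyed mapping."""
    from .synthetic import complexes_from_json

    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        out: list[ComplexRecord] = []
        for key in sorted(data):
            out.extend(complexes_from_json(data[key]))
        return out
    return complexes_from_json(data)


def read_flagged_proteins(path) -> set[str]:
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#") and line != "protein_id":
                out.add(line.split("\t")[0])
    return out


def write_pairs_tsv(path, pairs: list[ParalogPair]) -> None:
    rows = [
        "pair_id\ta\tb\tidentity\tcoverage\te_value\ttier\t"
        "same_domain_content\tohnolog"
    ]
    for p in sorted(pairs, key=lambda q: q.key):
        a, b = p.key
        same = "" if p.same_domain_content is None else int(p.same_domain_content)
        rows.append(
            f"{a}|{b}\t{a}\t{b}\t{p.best_identity:.2f}\t{p.best_coverage:.2f}\t"
            f"{p.best_e_value!r}\t{p.tier}\t{same}\t{int(p.ohnolog)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_edges_tsv(path, edges: list[EvidenceEdge]) -> None:
    rows = ["protein_a\tprotein_b\tdatabases\tdirections\tmethod_classes"]
    for e in sorted(edges, key=lambda x: x.key):
        rows.append(
            f"{e.protein_a}\t{e.protein_b}\t{';'.join(sorted(e.databases))}\t"
            f"{';'.join(sorted(e.directions))}\t"
            f"{';'.join(sorted(e.method_classes))}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_fates_tsv(path, assignments: list[FateAssignment]) -> None:
    rows = [
        "pair_id\tdataset\ttier\tfilter_level\tcriterion\tfate\t"
        "self_a\tself_b\tcross\tother_partner_a\tother_partner_b"
    ]
    for a in sorted(
        assignments,
        key=lambda x: (x.pair, x.dataset, x.filter_level, x.criterion),
    ):
        ev = a.evidence
        flags = (
            "\t".join(
                str(int(v))
                for v in (
                    ev.self_a,
                    ev.self_b,
                    ev.cross,
                    ev.other_partner_a,
                    ev.other_partner_b,
                )
            )
            if ev
            else "\t\t\t\t"
        )
        rows.append(
            f"{a.pair[0]}|{a.pair[1]}\t{a.dataset}\t{a.tier}\t"
            f"{a.filter_level}\t{a.criterion}\t{a.fate}\t{flags}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_transitions_tsv(path, records) -> None:
    rows = [
        "a_side_type\ta_ids\tb_pair\tb_fate\torder_a\torder_b\torder_relation"
    ]
    for r in sorted(records, key=lambda x: (x.b_pair, x.a_ids)):
        rows.append(
            f"{r.a_side_type}\t{';'.join(r.a_ids)}\t"
            f"{r.b_pair[0]}|{r.b_pair[1]}\t{r.b_fate}\t"
            f"{'' if r.a_order is None else r.a_order}\t"
            f"{'' if r.b_order is None else r.b_order}\t{r.order_relation}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
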