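"""The four canonical corpus analyses, as shipped query scripts.

``run_canonical`` compiles the packaged script for a query id and executes
it through the engine. ``oracle`` recomputes the same output table by
direct iteration over decoded records — no DSL, no aggregator states —
and exists purely as an independent verification path for tests.

Conventions shared by both paths: a "gene" is a feature with ftype exactly
``gene`` and an "exon" has ftype exactly ``exon`` (case-sensitive;
pseudogenes are not counted); the year buckets are ``ge2016`` (year >=
2016) and ``lt2016``; genomes appear under every clade named on their
lineage.
"""

from __future__ import annotations

import os
import statistics
from importlib import resources
from typing import Union

from ..dsl import QueryPlan, compile_source
from ..engine import OutputRow, OutputTable, run_query
from ..schema import GenomeRecord
from ..store import read_store

__all__ = ["QUERY_IDS", "load_script", "load_plan", "run_canonical", "oracle"]

QUERY_IDS = ("q1", "q2", "q3", "q4")

_SCRIPT_FILES = {
    "q1": "q1_extremes.bgq",
    "q2": "q2_exon_stats.bgq",
    "q3": "q3_assembler_popularity.bgq",
    "q4": "q4_assembly_quality.bgq",
}


def load_script(query_id: str) -> str:
    """Return the packaged source text for a canonical query id."""
    if query_id not in _SCRIPT_FILES:
        raise KeyError(f"unknown query id {query_id!r}; expected one of {QUERY_IDS}")
    ref = resources.files(__package__).joinpath("scripts", _SCRIPT_FILES[query_id])
    return ref.read_text(encoding="utf-8")


def load_plan(query_id: str) -> QueryPlan:
    return compile_source(load_script(query_id))


def run_canonical(query_id: str,
                  store_path: Union[str, os.PathLike],
                  workers: int = 1) -> OutputTable:
    """Run one canonical query over a store through the DSL + engine path."""
    return run_query(load_plan(query_id), store_path, workers=workers)


# ---------------------------------------------------------------------------
# direct-iteration oracle (tests only)

def _bucket(year: int) -> str:
    return "ge2016" if year >= 2016 else "lt2016"


def _gene_exon_tallies(record: GenomeRecord) -> tuple[int, int, int]:
    genes = exons = span = 0
    for s in record.sequences:
        for f in s.features:
            if f.ftype == "gene":
                genes += 1
                span += f.end - f.start + 1
            elif f.ftype == "exon":
                exons += 1
    return genes, exons, span


def _mean_sd_rows(rows: list[OutputRow], name: str, groups: dict) -> None:
    for key, values in groups.items():
        rows.append(OutputRow(name, key, statistics.fmean(values)))
        sd = statistics.stdev(values) if len(values) > 1 else 0.0
        rows.append(OutputRow(f"{name}_sd", key, sd))


def _oracle_q1(records) -> list[OutputRow]:
    best_max = best_min = None
    for r in records:
        key = (float(r.assembly.total_length), r.refseq_accession)
        if best_max is None or key[0] > best_max[0] or (key[0] == best_max[0] and key[1] < best_max[1]):
            best_max = key
        if best_min is None or key[0] < best_min[0] or (key[0] == best_min[0] and key[1] < best_min[1]):
            best_min = key
    rows = []
    if best_max is not None:
        rows.append(OutputRow("max_genome", (), (best_max[1], best_max[0])))
        rows.append(OutputRow("min_genome", (), (best_min[1], best_min[0])))
    return rows


def _oracle_q2(records) -> list[OutputRow]:
    species: dict = {}
    gene_num: dict = {}
    exon_num: dict = {}
    gene_len: dict = {}
    epg: dict = {}
    for r in records:
        genes, exons, span = _gene_exon_tallies(r)
        bucket = _bucket(r.release_year)
        for clade in r.lineage:
            key = (clade, bucket)
            species[key] = species.get(key, 0) + 1
            gene_num.setdefault(key, []).append(float(genes))
            if genes > 0:
                gene_len.setdefault(key, []).append(span / genes)
            if exons > 0:
                exon_num.setdefault(key, []).append(float(exons))
                if genes > 0:
                    epg.setdefault(key, []).append(exons / genes)
    rows = [OutputRow("species", key, n) for key, n in species.items()]
    _mean_sd_rows(rows, "gene_number", gene_num)
    _mean_sd_rows(rows, "exon_number", exon_num)
    _mean_sd_rows(rows, "gene_length", gene_len)
    _mean_sd_rows(rows, "exons_per_gene", epg)
    return rows


def _oracle_q3(records) -> list[OutputRow]:
    counts: dict = {}
    per_year: dict = {}
    for r in records:
        if "Bacteria" not in r.lineage:
            continue
        for a in r.assembly.assemblers:
            key = (a.name, r.release_year)
            counts[key] = counts.get(key, 0) + 1
            per_year.setdefault(r.release_year, {})
            per_year[r.release_year][a.name] = per_year[r.release_year].get(a.name, 0) + 1
    rows = [OutputRow("assembler_year", key, n) for key, n in counts.items()]
    for year, table in per_year.items():
        ranked = sorted(table.items(), key=lambda vc: (-vc[1], vc[0]))[:5]
        rows.append(OutputRow("top_assemblers", (year,), ranked))
    return rows


def _oracle_q4(records) -> list[OutputRow]:
    species: dict = {}
    stats: dict[str, dict] = {name: {} for name in (
        "total_length", "scaffold_count", "scaffold_n50",
        "contig_count", "contig_n50")}
    for r in records:
        if "Metazoa" not in r.lineage:
            continue
        bucket = _bucket(r.release_year)
        for a in r.assembly.assemblers:
            key = (a.name, bucket)
            species[key] = species.get(key, 0) + 1
            for name in stats:
                stats[name].setdefault(key, []).append(
                    float(getattr(r.assembly, name)))
    rows = [OutputRow("species", key, n) for key, n in species.items()]
    for name, groups in stats.items():
        _mean_sd_rows(rows, name, groups)
    return rows


def oracle(query_id: str, store_path: Union[str, os.PathLike]) -> OutputTable:
    """Recompute a canonical query by direct iteration (verification only).

    For queries with no matching records, mean/stdev outputs finalize as the
    "n=0" marker row, matching the engine's empty-input convention.
    """
    fn = {"q1": _oracle_q1, "q2": _oracle_q2, "q3": _oracle_q3, "q4": _oracle_q4}.get(query_id)
    if fn is None:
        raise KeyError(f"unknown query id {query_id!r}; expected one of {QUERY_IDS}")
    rows = fn(read_store(store_path))
    seen = {r.name for r in rows}
    for decl in load_plan(query_id).output_decls:
        if decl.agg_kind in ("mean", "stdev") and decl.name not in seen:
            rows.append(OutputRow(decl.name, (), "n=0"))
    rows.sort(key=lambda r: (r.name, r.indices))
    return OutputTable(rows=tuple(rows))
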