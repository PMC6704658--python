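"""Aggregator states, merge algebra, and the chunked query runner."""

import math
import statistics

import numpy as np
import pytest

from genoquery import store
from genoquery.dsl import compile_source
from genoquery.dsl.nodes import OutputDecl
from genoquery.engine import (
    agg_merge, agg_update, finalize, new_state, run_query, run_query_records,
)
from genoquery.queries import load_script

from conftest import make_record


def _decl(kind, arg=None):
    return OutputDecl(name="o", agg_kind=kind, agg_arg=arg, index_types=[],
                      value_type="float",
                      weight_type="float" if kind in ("maximum", "minimum") else None)


def _fold(kind, emissions):
    state = new_state(kind)
    for em in emissions:
        if isinstance(em, tuple):
            agg_update(state, em[0], em[1])
        else:
            agg_update(state, em)
    return state


@pytest.mark.parametrize("kind, emissions, expected", [
    ("sum", [1, 2, 3], 6),
    ("mean", [2.0, 4.0], 3.0),
    ("stdev", [5.0, 5.0, 5.0], 0.0),
    ("stdev", [2.0, 4.0], math.sqrt(2.0)),      # sample sd with n-1
    ("maximum", [("a", 3.0), ("b", 7.0), ("c", 7.0)], ("b", 7.0)),  # tie -> smaller value
    ("minimum", [("a", 3.0), ("b", 1.0), ("c", 1.0)], ("b", 1.0)),
    ("top", ["a", "a", "b", "b", "b", "c"], [("b", 3), ("a", 2)]),
])
def test_update_then_finalize_worked_values(kind, emissions, expected):
    value = finalize(_fold(kind, emissions), _decl(kind, arg=2))
    if isinstance(expected, float):
        assert value == pytest.approx(expected, abs=1e-12)
    else:
        assert value == expected


def test_mean_stdev_with_no_emissions_finalize_as_n0_marker():
    assert finalize(None, _decl("mean")) == "n=0"
    assert finalize(new_state("stdev"), _decl("stdev")) == "n=0"
    assert finalize(_fold("stdev", [3.0]), _decl("stdev")) == 0.0  # n=1 -> sd 0


def test_merge_worked_values():
    assert agg_merge(_fold("sum", [6]), _fold("sum", [4])).total == 10
    merged_top = agg_merge(_fold("top", ["a", "a"]), _fold("top", ["a", "b", "b", "b"]))
    assert merged_top.counts == {"a": 3, "b": 3}
    assert finalize(merged_top, _decl("top", arg=2)) == [("a", 3), ("b", 3)]


def test_stdev_chunk_merge_matches_single_pass():
    merged = agg_merge(_fold("stdev", [1.0, 2.0]), _fold("stdev", [3.0, 4.0]))
    single = _fold("stdev", [1.0, 2.0, 3.0, 4.0])
    assert merged.n == single.n
    assert abs(merged.acc - single.acc) <= 1e-12
    assert abs(merged.m2 - single.m2) <= 1e-12


def test_merge_is_associative_on_random_chunks():
    rng = np.random.default_rng(3)
    values = rng.normal(10.0, 4.0, size=30).tolist()
    a, b, c = _fold("stdev", values[:7]), _fold("stdev", values[7:16]), _fold("stdev", values[16:])
    left = agg_merge(agg_merge(a, b), c)
    right = agg_merge(a, agg_merge(b, c))
    assert left.n == right.n
    assert abs(left.m2 - right.m2) <= 1e-9
    sd = finalize(left, _decl("stdev"))
    assert sd == pytest.approx(statistics.stdev(values), abs=1e-9)


def test_merge_kind_mismatch_is_an_error():
    with pytest.raises(ValueError, match="cannot merge"):
        agg_merge(new_state("sum"), new_state("mean"))


def test_run_query_q1_three_genome_store(tmp_path):
    records = [
        make_record(accession="GCF_000000100.1", total_length=100),
        make_record(accession="GCF_000000220.1", total_length=220),
        make_record(accession="GCF_000004000.1", total_length=4000),
    ]
    path = tmp_path / "three.bgsf"
    store.write_store(records, path, block_records=2)
    table = run_query(compile_source(load_script("q1")), path)
    result = {r.name: r.value for r in table.rows}
    assert result["max_genome"] == ("GCF_000004000.1", 4000.0)
    assert result["min_genome"] == ("GCF_000000100.1", 100.0)


def test_run_query_empty_store(tmp_path):
    path = tmp_path / "empty.bgsf"
    store.write_store([], path)
    src = ("g: Genome = input;\n"
           "m: output mean of float;\n"
           "x: output maximum of string weight float;\n"
           "t: output top(3) of string;\n"
           "emit m << float(g.taxid);\n"
           "emit x << g.refseq_accession weight float(g.taxid);\n"
           "emit t << g.refseq_accession;\n")
    table = run_query(compile_source(src), path)
    assert [(r.name, r.value) for r in table.rows] == [("m", "n=0")]


def test_run_query_worker_counts_agree(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1", total_length=1000 + 7 * i,
                           n_exons=i % 5, lineage=("Eukaryota", "Metazoa"))
               for i in range(40)]
    path = tmp_path / "forty.bgsf"
    store.write_store(records, path, block_records=6)
    plan = compile_source(load_script("q2"))
    reference = run_query(plan, path, workers=1).to_tsv()
    for workers in (2, 4):
        assert run_query(plan, path, workers=workers).to_tsv() == reference


def test_run_query_names_failing_record():
    src = ("g: Genome = input;\n"
           "s: output sum of int;\n"
           "emit s << g.sequences[99].length;\n")
    plan = compile_source(src)
    record = make_record(accession="GCF_000000033.1")
    with pytest.raises(Exception, match="GCF_000000033.1"):
        run_query_records(plan, [[record]])


def test_indexed_sum_partitions_emissions(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1",
                           year=2014 + (i % 4)) for i in range(20)]
    path = tmp_path / "part.bgsf"
    store.write_store(records, path, block_records=3)
    src = ("g: Genome = input;\n"
           "by_year: output sum[int] of int;\n"
           "emit by_year[g.release_year] << 1;\n")
    table = run_query(compile_source(src), path)
    assert sum(r.value for r in table.rows) == len(records)
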