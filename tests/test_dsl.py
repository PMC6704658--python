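"""Query language front end: lexing, parsing, typing, compiled semantics."""

import copy

import pytest

from genoquery import dsl
from genoquery.dsl import (
    DslSyntaxError, QueryCompileError, compile_source, parse_source, to_source,
    tokenize, typecheck,
)
from genoquery.queries import QUERY_IDS, load_script

from conftest import make_record

Q1 = load_script("q1")


def test_tokenize_emit_statement():
    tokens = tokenize("emit x << 1;")
    assert [t.kind for t in tokens] == ["emit", "IDENT", "<<", "INT", ";", "EOF"]
    assert (tokens[0].line, tokens[0].col) == (1, 1)


def test_tokenize_empty_source_is_only_end_marker():
    assert [t.kind for t in tokenize("")] == ["EOF"]


def test_tokenize_illegal_character_position():
    with pytest.raises(DslSyntaxError, match=r"1:1"):
        tokenize("@")


def test_tokenize_skips_comments_and_tracks_lines():
    tokens = tokenize("# a comment\nemit x << 1;")
    assert tokens[0].kind == "emit"
    assert tokens[0].line == 2


def test_parse_q1_structure():
    program = parse_source(Q1)
    assert program.input_var == "g"
    assert [d.agg_kind for d in program.output_decls] == ["maximum", "minimum"]
    assert [d.weight_type for d in program.output_decls] == ["float", "float"]
    assert len(program.statements) == 2


def test_parse_missing_semicolon_names_position():
    src = "g: Genome = input;\nx: output sum of int;\nemit x << 1\n"
    with pytest.raises(DslSyntaxError, match=r"4:"):
        parse_source(src)


def test_parser_accepts_top_zero_typecheck_rejects_it():
    src = ("g: Genome = input;\n"
           "t: output top(0)[int] of string;\n"
           "emit t[1] << g.refseq_accession;\n")
    program = parse_source(src)  # no syntax error
    errors = typecheck(program)
    assert any("top argument must be >= 1" in str(e) for e in errors)


@pytest.mark.parametrize("source, fragment", [
    # emit with 1 index into a 0-index output
    ("g: Genome = input;\ns: output sum of int;\nemit s[1] << 1;\n",
     "0 index(es)"),
    # undeclared output
    ("g: Genome = input;\nemit nothing << 1;\n", "undeclared output"),
    # unknown field on a domain type
    ("g: Genome = input;\ns: output sum of int;\nemit s << g.bogus;\n",
     "no field 'bogus'"),
    # weight emitted without a weight declaration
    ("g: Genome = input;\ns: output sum of int;\nemit s << 1 weight 2.0;\n",
     "not declared with a weight"),
    # maximum requires a weight type
    ("g: Genome = input;\nm: output maximum of string;\n"
     "emit m << g.refseq_accession;\n", "requires a 'weight'"),
    # iteration over a non-list
    ("g: Genome = input;\ns: output sum of int;\n"
     "foreach (x: int in g.taxid) { emit s << x; }\n", "needs a list"),
    # value type mismatch
    ("g: Genome = input;\ns: output sum of int;\nemit s << \"nope\";\n",
     "takes int values"),
    # stdev must be numeric
    ("g: Genome = input;\nd: output stdev of string;\nemit d << \"x\";\n",
     "requires a numeric value type"),
])
def test_typecheck_rejections(source, fragment):
    errors = typecheck(parse_source(source))
    assert any(fragment in str(e) for e in errors), [str(e) for e in errors]


def test_typecheck_q1_is_clean():
    assert typecheck(parse_source(Q1)) == []


def test_foreach_element_type_comes_from_field_table():
    src = ("g: Genome = input;\n"
           "s: output sum of int;\n"
           "foreach (f: Feature in g.sequences[0].features) {\n"
           "    emit s << f.end - f.start + 1;\n"
           "}\n")
    assert typecheck(parse_source(src)) == []
    # wrong element annotation is caught
    bad = src.replace("f: Feature", "f: Sequence")
    errors = typecheck(parse_source(bad))
    assert any("declared Sequence but list holds Feature" in str(e) for e in errors)


def test_compile_q1_emission_semantics():
    plan = compile_source(Q1)
    record = make_record(total_length=4000)
    emissions = plan.record_fn(record)
    assert [(e.output, e.value, e.weight) for e in emissions] == [
        ("max_genome", record.refseq_accession, 4000.0),
        ("min_genome", record.refseq_accession, 4000.0),
    ]


def test_compile_foreach_emits_once_per_element():
    src = ("g: Genome = input;\n"
           "n: output sum of int;\n"
           "foreach (s: Sequence in g.sequences) {\n"
           "    foreach (f: Feature in s.features) {\n"
           "        if (f.ftype == \"exon\") { emit n << 1; }\n"
           "    }\n"
           "}\n")
    plan = compile_source(src)
    record = make_record(n_exons=3)
    assert len(plan.record_fn(record)) == 3


def test_record_fn_is_pure_and_does_not_mutate():
    plan = compile_source(load_script("q2"))
    record = make_record(n_exons=4, lineage=("Eukaryota", "Metazoa"))
    before = copy.deepcopy(record)
    first = plan.record_fn(record)
    second = plan.record_fn(record)
    assert first == second
    assert record == before


def test_compile_rejects_ill_typed_program():
    with pytest.raises(QueryCompileError, match="type errors"):
        compile_source("g: Genome = input;\nemit ghost << 1;\n")


@pytest.mark.parametrize("query_id", QUERY_IDS)
def test_shipped_scripts_pretty_print_round_trip(query_id):
    program = parse_source(load_script(query_id))
    assert typecheck(program) == []
    reparsed = parse_source(to_source(program))
    assert reparsed == program


def _eval_int_expr(expr: str, record=None):
    src = f"g: Genome = input;\nr: output sum of int;\nemit r << {expr};\n"
    plan = compile_source(src)
    return plan.record_fn(record or make_record())[0].value


@pytest.mark.parametrize("expr, expected", [
    ("7 / 2", 3),
    ("0 - 7 / 2", -3),        # truncation toward zero, not floor
    ("(0 - 7) / 2", -3),
    ("7 % 3", 1),
    ("(0 - 7) % 3", -1),      # remainder keeps the dividend's sign
    ("2 + 3 * 4", 14),
    ("len(g.lineage)", 1),
    ("int(2.9)", 2),
])
def test_arithmetic_semantics(expr, expected):
    assert _eval_int_expr(expr) == expected


def test_mixed_arithmetic_promotes_to_float():
    src = "g: Genome = input;\nr: output sum of float;\nemit r << 7 / 2.0;\n"
    assert compile_source(src).record_fn(make_record())[0].value == 3.5


def test_string_builtins_and_indexing():
    src = ("g: Genome = input;\n"
           "r: output sum[string] of int;\n"
           "emit r[uppercase(g.lineage[0])] << 1;\n")
    emission = compile_source(src).record_fn(make_record())[0]
    assert emission.indices == ("BACTERIA",)
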