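"""Query language front end: lexer, parser, type checker, compiler.

Typical use::

    from genoquery import dsl
    plan = dsl.compile_source(open("query.bgq").read())
    emissions = plan.record_fn(record)
"""

from .lexer import DslSyntaxError, Token, tokenize
from .nodes import Program, OutputDecl, to_source
from .parser import parse, parse_source
from .typecheck import TypeError_, typecheck
from .compiler import Emission, QueryCompileError, QueryPlan, compile_program

__all__ = [
    "DslSyntaxError", "Token", "tokenize",
    "Program", "OutputDecl", "to_source",
    "parse", "parse_source",
    "TypeError_", "typecheck",
    "Emission", "QueryCompileError", "QueryPlan", "compile_program",
    "compile_source",
]


def compile_source(source: str) -> QueryPlan:
    """Tokenize, parse, type-check and compile query source text."""
    return compile_program(parse_source(source), source=source)
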