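"""Compiles a type-checked program into an executable QueryPlan.

The plan's per-record function is pure: applied to one GenomeRecord it
returns the list of emissions produced by the program for that record, with
no state carried across records and no mutation of the input. Each AST node
compiles to a small closure; the environment is a plain dict keyed by
variable name.

Runtime conventions pinned here:

* int / int divides with truncation toward zero (C semantics); % is the
  matching truncated remainder; mixed int/float arithmetic promotes to float.
* Absent optional schema fields read as: score -> 0.0, phase -> -1,
  parent -> "", seq -> "".
* An int emitted into a float-declared output (value, weight, or index of
  type float) is promoted to float at emission time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from ..schema import GenomeRecord
from .nodes import (
    Assign, Binary, BoolLit, Call, Decl, Emit, Expr, FieldAccess, FloatLit,
    Foreach, IfStmt, IndexExpr, IntLit, OutputDecl, Program, Stmt, StringLit,
    Unary, Var,
)
from .typecheck import FLOAT, INT, typecheck

__all__ = ["Emission", "QueryPlan", "compile_program", "QueryCompileError"]


class QueryCompileError(ValueError):
    """Raised when compiling a program that failed type checking."""


@dataclass(frozen=True)
class Emission:
    """One value emitted to an output aggregator by one record."""

    output: str
    indices: tuple
    value: object
    weight: Optional[object] = None


@dataclass(frozen=True)
class QueryPlan:
    """Compiled program: output declarations + pure per-record emit function."""

    output_decls: tuple[OutputDecl, ...]
    record_fn: Callable[[GenomeRecord], list[Emission]]
    source: str = ""


_OPTIONAL_DEFAULTS = {"score": 0.0, "phase": -1, "parent": "", "seq": ""}


def _trunc_div(a: int, b: int) -> int:
    q = abs(a) // abs(b)
    return -q if (a < 0) != (b < 0) else q


def _trunc_mod(a: int, b: int) -> int:
    return a - b * _trunc_div(a, b)


def _compile_expr(e: Expr) -> Callable[[dict], object]:
    if isinstance(e, (IntLit, FloatLit, StringLit, BoolLit)):
        v = e.value
        return lambda env: v
    if isinstance(e, Var):
        name = e.name
        return lambda env: env[name]
    if isinstance(e, FieldAccess):
        obj = _compile_expr(e.obj)
        name = e.name
        if name in _OPTIONAL_DEFAULTS:
            default = _OPTIONAL_DEFAULTS[name]

            def access(env):
                v = getattr(obj(env), name)
                return default if v is None else v
            return access
        return lambda env: getattr(obj(env), name)
    if isinstance(e, IndexExpr):
        obj = _compile_expr(e.obj)
        idx = _compile_expr(e.index)

        def index(env):
            lst = obj(env)
            i = idx(env)
            if not 0 <= i < len(lst):
                raise IndexError(f"list index {i} out of range (length {len(lst)})")
            return lst[i]
        return index
    if isinstance(e, Unary):
        operand = _compile_expr(e.operand)
        if e.op == "-":
            return lambda env: -operand(env)
        return lambda env: not operand(env)
    if isinstance(e, Binary):
        return _compile_binary(e)
    if isinstance(e, Call):
        return _compile_call(e)
    raise TypeError(f"unknown expression node {e!r}")


def _compile_binary(e: Binary) -> Callable[[dict], object]:
    op = e.op
    left = _compile_expr(e.left)
    right = _compile_expr(e.right)
    if op == "&&":
        return lambda env: bool(left(env)) and bool(right(env))
    if op == "||":
        return lambda env: bool(left(env)) or bool(right(env))
    if op == "/":
        both_int = getattr(e.left, "ty", None) is INT and getattr(e.right, "ty", None) is INT
        if both_int:
            return lambda env: _trunc_div(left(env), right(env))
        return lambda env: left(env) / right(env)
    if op == "%":
        return lambda env: _trunc_mod(left(env), right(env))
    fn = {
        "+": lambda a, b: a + b,
        "-": lambda a, b: a - b,
        "*": lambda a, b: a * b,
        "==": lambda a, b: a == b,
        "!=": lambda a, b: a != b,
        "<": lambda a, b: a < b,
        "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b,
        ">=": lambda a, b: a >= b,
    }[op]
    return lambda env: fn(left(env), right(env))


def _format_value(v: object) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _compile_call(e: Call) -> Callable[[dict], object]:
    args = [_compile_expr(a) for a in e.args]
    name = e.name
    if name == "len":
        a0 = args[0]
        return lambda env: len(a0(env))
    if name == "lowercase":
        a0 = args[0]
        return lambda env: a0(env).lower()
    if name == "uppercase":
        a0 = args[0]
        return lambda env: a0(env).upper()
    if name == "int":
        a0 = args[0]
        return lambda env: int(a0(env))
    if name == "float":
        a0 = args[0]
        return lambda env: float(a0(env))
    if name == "string":
        a0 = args[0]
        return lambda env: _format_value(a0(env))
    if name == "list_contains":
        a0, a1 = args
        return lambda env: a1(env) in a0(env)
    if name == "str_contains":
        a0, a1 = args
        return lambda env: a1(env) in a0(env)
    raise AssertionError(f"unknown builtin {name}")


def _compile_stmt(s: Stmt, decls: dict[str, OutputDecl]) -> Callable[[dict, list], None]:
    if isinstance(s, Emit):
        decl = decls[s.output]
        output = s.output
        index_fns = [_compile_expr(i) for i in s.indices]
        idx_float = [t == "float" for t in decl.index_types]
        value_fn = _compile_expr(s.value)
        value_float = decl.value_type == "float"
        weight_fn = _compile_expr(s.weight) if s.weight is not None else None
        weight_float = decl.weight_type == "float"

        def run(env, emissions):
            indices = tuple(
                float(f(env)) if promote else f(env)
                for f, promote in zip(index_fns, idx_float))
            value = value_fn(env)
            if value_float:
                value = float(value)
            weight = None
            if weight_fn is not None:
                weight = weight_fn(env)
                if weight_float:
                    weight = float(weight)
            emissions.append(Emission(output, indices, value, weight))
        return run
    if isinstance(s, Foreach):
        var = s.var
        iterable = _compile_expr(s.iterable)
        body = [_compile_stmt(b, decls) for b in s.body]

        def run_foreach(env, emissions):
            for item in iterable(env):
                env[var] = item
                for b in body:
                    b(env, emissions)
            env.pop(var, None)
        return run_foreach
    if isinstance(s, IfStmt):
        cond = _compile_expr(s.cond)
        then = [_compile_stmt(b, decls) for b in s.then]
        orelse = [_compile_stmt(b, decls) for b in s.orelse]

        def run_if(env, emissions):
            branch = then if cond(env) else orelse
            for b in branch:
                b(env, emissions)
        return run_if
    if isinstance(s, (Decl, Assign)):
        name = s.name
        expr = _compile_expr(s.expr)
        to_float = isinstance(s, Decl) and s.var_type == "float"
        if to_float:
            def run_decl(env, emissions):
                env[name] = float(expr(env))
            return run_decl

        def run_assign(env, emissions):
            env[name] = expr(env)
        return run_assign
    raise TypeError(f"unknown statement node {s!r}")


def compile_program(program: Program, source: str = "") -> QueryPlan:
    """Compile a parsed program; type-checks first and raises on errors."""
    errors = typecheck(program)
    if errors:
        raise QueryCompileError(
            "program has type errors:\n" + "\n".join(str(e) for e in errors))
    decls = {d.name: d for d in program.output_decls}
    stmts = [_compile_stmt(s, decls) for s in program.statements]
    input_var = program.input_var

    def record_fn(record: GenomeRecord) -> list[Emission]:
        env: dict[str, object] = {input_var: record}
        emissions: list[Emission] = []
        for s in stmts:
            s(env, emissions)
        return emissions

    return QueryPlan(output_decls=tuple(program.output_decls),
                     record_fn=record_fn, source=source)
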