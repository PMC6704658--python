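"""AST node types for the query language, plus a pretty-printer.

Node equality ignores source positions (``pos`` fields compare=False), so a
pretty-printed program reparses to an equal AST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "Pos", "Expr", "IntLit", "FloatLit", "StringLit", "BoolLit", "Var",
    "FieldAccess", "IndexExpr", "Unary", "Binary", "Call",
    "Stmt", "Emit", "Foreach", "IfStmt", "Decl", "Assign",
    "OutputDecl", "Program", "to_source",
]


@dataclass(frozen=True)
class Pos:
    line: int = 0
    col: int = 0


def _pos_field():
    return field(default_factory=Pos, compare=False, repr=False)


# --- expressions -----------------------------------------------------------

@dataclass
class IntLit:
    value: int
    pos: Pos = _pos_field()


@dataclass
class FloatLit:
    value: float
    pos: Pos = _pos_field()


@dataclass
class StringLit:
    value: str
    pos: Pos = _pos_field()


@dataclass
class BoolLit:
    value: bool
    pos: Pos = _pos_field()


@dataclass
class Var:
    name: str
    pos: Pos = _pos_field()


@dataclass
class FieldAccess:
    obj: "Expr"
    name: str
    pos: Pos = _pos_field()


@dataclass
class IndexExpr:
    obj: "Expr"
    index: "Expr"
    pos: Pos = _pos_field()


@dataclass
class Unary:
    op: str  # "-" or "!"
    operand: "Expr"
    pos: Pos = _pos_field()


@dataclass
class Binary:
    op: str
    left: "Expr"
    right: "Expr"
    pos: Pos = _pos_field()


@dataclass
class Call:
    name: str
    args: list["Expr"]
    pos: Pos = _pos_field()


Expr = Union[IntLit, FloatLit, StringLit, BoolLit, Var, FieldAccess,
             IndexExpr, Unary, Binary, Call]


# --- statements ------------------------------------------------------------

@dataclass
class Emit:
    output: str
    indices: list[Expr]
    value: Expr
    weight: Optional[Expr] = None
    pos: Pos = _pos_field()


@dataclass
class Foreach:
    var: str
    var_type: str
    iterable: Expr
    body: list["Stmt"]
    pos: Pos = _pos_field()


@dataclass
class IfStmt:
    cond: Expr
    then: list["Stmt"]
    orelse: list["Stmt"] = field(default_factory=list)
    pos: Pos = _pos_field()


@dataclass
class Decl:
    name: str
    var_type: str
    expr: Expr
    pos: Pos = _pos_field()


@dataclass
class Assign:
    name: str
    expr: Expr
    pos: Pos = _pos_field()


Stmt = Union[Emit, Foreach, IfStmt, Decl, Assign]


@dataclass
class OutputDecl:
    name: str
    agg_kind: str  # sum | mean | maximum | minimum | top | stdev
    agg_arg: Optional[int]
    index_types: list[str]
    value_type: str
    weight_type: Optional[str] = None
    pos: Pos = _pos_field()


@dataclass
class Program:
    input_var: str
    output_decls: list[OutputDecl]
    statements: list[Stmt]
    pos: Pos = _pos_field()


# --- pretty printer --------------------------------------------------------

_PRECEDENCE = {
    "||": 1, "&&": 2,
    "==": 3, "!=": 3,
    "<": 4, "<=": 4, ">": 4, ">=": 4,
    "+": 5, "-": 5,
    "*": 6, "/": 6, "%": 6,
}


def _expr_src(e: Expr, parent_prec: int = 0) -> str:
    if isinstance(e, IntLit):
        return str(e.value)
    if isinstance(e, FloatLit):
        return repr(e.value)
    if isinstance(e, StringLit):
        body = e.value.replace("\\", "\\\\").replace('"', '\\"')
        body = body.replace("\n", "\\n").replace("\t", "\\t")
        return f'"{body}"'
    if isinstance(e, BoolLit):
        return "true" if e.value else "false"
    if isinstance(e, Var):
        return e.name
    if isinstance(e, FieldAccess):
        return f"{_expr_src(e.obj, 10)}.{e.name}"
    if isinstance(e, IndexExpr):
        return f"{_expr_src(e.obj, 10)}[{_expr_src(e.index)}]"
    if isinstance(e, Unary):
        return f"{e.op}{_expr_src(e.operand, 9)}"
    if isinstance(e, Binary):
        prec = _PRECEDENCE[e.op]
        src = f"{_expr_src(e.left, prec)} {e.op} {_expr_src(e.right, prec + 1)}"
        return f"({src})" if prec < parent_prec else src
    if isinstance(e, Call):
        return f"{e.name}({', '.join(_expr_src(a) for a in e.args)})"
    raise TypeError(f"unknown expression node {e!r}")


def _stmt_src(s: Stmt, indent: int) -> list[str]:
    pad = "    " * indent
    if isinstance(s, Emit):
        idx = "".join(f"[{_expr_src(i)}]" for i in s.indices)
        line = f"{pad}emit {s.output}{idx} << {_expr_src(s.value)}"
        if s.weight is not None:
            line += f" weight {_expr_src(s.weight)}"
        return [line + ";"]
    if isinstance(s, Foreach):
        lines = [f"{pad}foreach ({s.var}: {s.var_type} in {_expr_src(s.iterable)}) {{"]
        for b in s.body:
            lines.extend(_stmt_src(b, indent + 1))
        lines.append(pad + "}")
        return lines
    if isinstance(s, IfStmt):
        lines = [f"{pad}if ({_expr_src(s.cond)}) {{"]
        for b in s.then:
            lines.extend(_stmt_src(b, indent + 1))
        if s.orelse:
            lines.append(pad + "} else {")
            for b in s.orelse:
                lines.extend(_stmt_src(b, indent + 1))
        lines.append(pad + "}")
        return lines
    if isinstance(s, Decl):
        return [f"{pad}{s.name}: {s.var_type} = {_expr_src(s.expr)};"]
    if isinstance(s, Assign):
        return [f"{pad}{s.name} = {_expr_src(s.expr)};"]
    raise TypeError(f"unknown statement node {s!r}")


def to_source(program: Program) -> str:
    """Render a Program back to source text that reparses to an equal AST."""
    lines = [f"{program.input_var}: Genome = input;"]
    for d in program.output_decls:
        agg = d.agg_kind + (f"({d.agg_arg})" if d.agg_arg is not None else "")
        idx = "".join(f"[{t}]" for t in d.index_types)
        line = f"{d.name}: output {agg}{idx} of {d.value_type}"
        if d.weight_type is not None:
            line += f" weight {d.weight_type}"
        lines.append(line + ";")
    for s in program.statements:
        lines.extend(_stmt_src(s, 0))
    return "\n".join(lines) + "\n"
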