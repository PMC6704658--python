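"""Static type checker for parsed query programs.

Annotates every expression node with a ``ty`` attribute and returns the
list of type errors (empty list = well typed). The domain field table
mirrors the schema record types exactly; optional schema fields (score,
phase, parent, seq) read as their scalar type, with documented defaults at
run time for absent values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .nodes import (
    Assign, Binary, BoolLit, Call, Decl, Emit, Expr, FieldAccess, FloatLit,
    Foreach, IfStmt, IndexExpr, IntLit, OutputDecl, Pos, Program, Stmt,
    StringLit, Unary, Var,
)

__all__ = [
    "Type", "INT", "FLOAT", "STRING", "BOOL", "ERROR",
    "DomainType", "ArrayType", "TypeError_", "typecheck", "resolve_type",
    "FIELD_TABLE", "GENOME",
]


@dataclass(frozen=True)
class Type:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class DomainType(Type):
    pass


@dataclass(frozen=True)
class ArrayType(Type):
    elem: Type = None  # type: ignore[assignment]

    def __str__(self) -> str:
        return f"array of {self.elem}"


INT = Type("int")
FLOAT = Type("float")
STRING = Type("string")
BOOL = Type("bool")
ERROR = Type("<error>")  # unifies with anything to suppress cascades

GENOME = DomainType("Genome")
SEQUENCE = DomainType("Sequence")
FEATURE = DomainType("Feature")
ATTRIBUTE = DomainType("Attribute")
ASSEMBLER = DomainType("Assembler")
ASSEMBLY = DomainType("Assembly")

_SCALARS = {"int": INT, "float": FLOAT, "string": STRING, "bool": BOOL}
_DOMAINS = {t.name: t for t in (GENOME, SEQUENCE, FEATURE, ATTRIBUTE, ASSEMBLER, ASSEMBLY)}


def resolve_type(name: str) -> Type:
    if name in _SCALARS:
        return _SCALARS[name]
    if name in _DOMAINS:
        return _DOMAINS[name]
    raise KeyError(name)


def _arr(elem: Type) -> ArrayType:
    return ArrayType(name="array", elem=elem)


FIELD_TABLE: dict[Type, dict[str, Type]] = {
    GENOME: {
        "refseq_accession": STRING,
        "taxid": INT,
        "organism_name": STRING,
        "lineage": _arr(STRING),
        "release_year": INT,
        "assembly": ASSEMBLY,
        "sequences": _arr(SEQUENCE),
    },
    ASSEMBLY: {
        "assemblers": _arr(ASSEMBLER),
        "total_length": INT,
        "total_gap_length": INT,
        "scaffold_n50": INT,
        "scaffold_count": INT,
        "contig_n50": INT,
        "contig_count": INT,
    },
    SEQUENCE: {
        "header": STRING,
        "accession": STRING,
        "length": INT,
        "features": _arr(FEATURE),
        "seq": STRING,
    },
    FEATURE: {
        "seqid": STRING,
        "source": STRING,
        "ftype": STRING,
        "start": INT,
        "end": INT,
        "score": FLOAT,
        "strand": STRING,
        "phase": INT,
        "attributes": _arr(ATTRIBUTE),
        "parent": STRING,
    },
    ATTRIBUTE: {"tag": STRING, "value": STRING},
    ASSEMBLER: {"name": STRING, "desc": STRING},
}

# builtin name -> (argument spec, result type); None in an arg slot = checked ad hoc
_BUILTINS = {
    "len": 1, "lowercase": 1, "uppercase": 1,
    "int": 1, "float": 1, "string": 1,
    "list_contains": 2, "str_contains": 2,
}


@dataclass(frozen=True)
class TypeError_:
    message: str
    pos: Pos

    def __str__(self) -> str:
        return f"{self.pos.line}:{self.pos.col}: {self.message}"


def _is_numeric(t: Type) -> bool:
    return t in (INT, FLOAT, ERROR)


class _Checker:
    def __init__(self, program: Program):
        self.program = program
        self.errors: list[TypeError_] = []
        self.env: dict[str, Type] = {program.input_var: GENOME}
        self.outputs: dict[str, OutputDecl] = {}

    def err(self, message: str, pos: Pos) -> Type:
        self.errors.append(TypeError_(message, pos))
        return ERROR

    # -- declarations --------------------------------------------------------

    def check_output_decl(self, d: OutputDecl) -> None:
        if d.name in self.outputs:
            self.err(f"output {d.name!r} declared twice", d.pos)
        self.outputs[d.name] = d
        if d.name in self.env:
            self.err(f"output name {d.name!r} collides with a variable", d.pos)
        if d.agg_kind == "top":
            if d.agg_arg is None:
                self.err("top requires an integer argument, e.g. top(5)", d.pos)
            elif d.agg_arg < 1:
                self.err(f"top argument must be >= 1, got {d.agg_arg}", d.pos)
        elif d.agg_arg is not None:
            self.err(f"aggregator {d.agg_kind!r} takes no argument", d.pos)
        for t in d.index_types:
            if t not in _SCALARS:
                self.err(f"index type must be scalar, got {t!r}", d.pos)
        if d.value_type not in _SCALARS:
            self.err(f"output value type must be scalar, got {d.value_type!r}", d.pos)
        if d.agg_kind in ("sum", "mean", "stdev"):
            if d.value_type not in ("int", "float"):
                self.err(f"{d.agg_kind} requires a numeric value type, got {d.value_type!r}", d.pos)
            if d.weight_type is not None:
                self.err(f"{d.agg_kind} does not take a weight", d.pos)
        elif d.agg_kind in ("maximum", "minimum"):
            if d.weight_type is None:
                self.err(f"{d.agg_kind} requires a 'weight' type (the comparison key)", d.pos)
            elif d.weight_type not in ("int", "float"):
                self.err(f"{d.agg_kind} weight must be numeric, got {d.weight_type!r}", d.pos)
        elif d.agg_kind == "top":
            if d.weight_type is not None:
                self.err("top does not take a weight", d.pos)

    # -- expressions ---------------------------------------------------------

    def infer(self, e: Expr) -> Type:
        ty = self._infer(e)
        e.ty = ty  # annotation used by the compiler
        return ty

    def _infer(self, e: Expr) -> Type:
        if isinstance(e, IntLit):
            return INT
        if isinstance(e, FloatLit):
            return FLOAT
        if isinstance(e, StringLit):
            return STRING
        if isinstance(e, BoolLit):
            return BOOL
        if isinstance(e, Var):
            if e.name not in self.env:
                return self.err(f"undefined variable {e.name!r}", e.pos)
            return self.env[e.name]
        if isinstance(e, FieldAccess):
            obj_t = self.infer(e.obj)
            if obj_t is ERROR:
                return ERROR
            table = FIELD_TABLE.get(obj_t)
            if table is None:
                return self.err(f"type {obj_t} has no fields", e.pos)
            if e.name not in table:
                return self.err(f"type {obj_t} has no field {e.name!r}", e.pos)
            return table[e.name]
        if isinstance(e, IndexExpr):
            obj_t = self.infer(e.obj)
            idx_t = self.infer(e.index)
            if idx_t not in (INT, ERROR):
                self.err(f"list index must be int, got {idx_t}", e.pos)
            if obj_t is ERROR:
                return ERROR
            if not isinstance(obj_t, ArrayType):
                return self.err(f"cannot index into {obj_t}", e.pos)
            return obj_t.elem
        if isinstance(e, Unary):
            t = self.infer(e.operand)
            if e.op == "-":
                if not _is_numeric(t):
                    return self.err(f"unary '-' needs a numeric operand, got {t}", e.pos)
                return t
            if t not in (BOOL, ERROR):
                return self.err(f"'!' needs a bool operand, got {t}", e.pos)
            return BOOL
        if isinstance(e, Binary):
            return self._infer_binary(e)
        if isinstance(e, Call):
            return self._infer_call(e)
        raise TypeError(f"unknown expression node {e!r}")

    def _infer_binary(self, e: Binary) -> Type:
        lt = self.infer(e.left)
        rt = self.infer(e.right)
        op = e.op
        if ERROR in (lt, rt):
            return ERROR
        if op in ("&&", "||"):
            if lt is not BOOL or rt is not BOOL:
                return self.err(f"{op!r} needs bool operands, got {lt} and {rt}", e.pos)
            return BOOL
        if op in ("==", "!="):
            same = lt == rt or (_is_numeric(lt) and _is_numeric(rt))
            if not same:
                return self.err(f"cannot compare {lt} with {rt}", e.pos)
            return BOOL
        if op in ("<", "<=", ">", ">="):
            ok = (_is_numeric(lt) and _is_numeric(rt)) or (lt is STRING and rt is STRING)
            if not ok:
                return self.err(f"cannot order {lt} and {rt}", e.pos)
            return BOOL
        # arithmetic
        if op == "+" and lt is STRING and rt is STRING:
            return STRING
        if not (_is_numeric(lt) and _is_numeric(rt)):
            return self.err(f"operator {op!r} needs numeric operands, got {lt} and {rt}", e.pos)
        if op == "%" and (lt is not INT or rt is not INT):
            return self.err("'%' is defined on int operands only", e.pos)
        return FLOAT if FLOAT in (lt, rt) else INT

    def _infer_call(self, e: Call) -> Type:
        if e.name not in _BUILTINS:
            return self.err(f"unknown function {e.name!r}", e.pos)
        arity = _BUILTINS[e.name]
        if len(e.args) != arity:
            return self.err(
                f"{e.name}() takes {arity} argument(s), got {len(e.args)}", e.pos)
        arg_ts = [self.infer(a) for a in e.args]
        if ERROR in arg_ts:
            return ERROR
        name = e.name
        if name == "len":
            if not isinstance(arg_ts[0], ArrayType) and arg_ts[0] is not STRING:
                return self.err(f"len() needs a list or string, got {arg_ts[0]}", e.pos)
            return INT
        if name in ("lowercase", "uppercase"):
            if arg_ts[0] is not STRING:
                return self.err(f"{name}() needs a string, got {arg_ts[0]}", e.pos)
            return STRING
        if name in ("int", "float"):
            if arg_ts[0] not in (INT, FLOAT, STRING, BOOL):
                return self.err(f"{name}() cannot convert {arg_ts[0]}", e.pos)
            return INT if name == "int" else FLOAT
        if name == "string":
            if arg_ts[0] not in (INT, FLOAT, STRING, BOOL):
                return self.err(f"string() cannot convert {arg_ts[0]}", e.pos)
            return STRING
        if name == "list_contains":
            if not (isinstance(arg_ts[0], ArrayType) and arg_ts[0].elem is STRING):
                return self.err(
                    f"list_contains() needs a list of string, got {arg_ts[0]}", e.pos)
            if arg_ts[1] is not STRING:
                return self.err(
                    f"list_contains() needs a string to look for, got {arg_ts[1]}", e.pos)
            return BOOL
        if name == "str_contains":
            if arg_ts[0] is not STRING or arg_ts[1] is not STRING:
                return self.err("str_contains() needs two strings", e.pos)
            return BOOL
        raise AssertionError(name)

    # -- statements ----------------------------------------------------------

    def _assignable(self, target: Type, value: Type) -> bool:
        if ERROR in (target, value):
            return True
        if target == value:
            return True
        return target is FLOAT and value is INT  # implicit int -> float

    def check_stmt(self, s: Stmt) -> None:
        if isinstance(s, Emit):
            self.check_emit(s)
        elif isinstance(s, Foreach):
            it_t = self.infer(s.iterable)
            try:
                elem_declared = resolve_type(s.var_type)
            except KeyError:
                elem_declared = self.err(f"unknown type {s.var_type!r}", s.pos)
            if it_t is not ERROR:
                if not isinstance(it_t, ArrayType):
                    self.err(f"foreach needs a list to iterate, got {it_t}", s.pos)
                elif elem_declared not in (ERROR,) and it_t.elem != elem_declared:
                    self.err(
                        f"foreach variable declared {elem_declared} but list holds {it_t.elem}",
                        s.pos)
            if s.var in self.env:
                self.err(f"variable {s.var!r} already declared", s.pos)
            self.env[s.var] = elem_declared
            for b in s.body:
                self.check_stmt(b)
            del self.env[s.var]
        elif isinstance(s, IfStmt):
            cond_t = self.infer(s.cond)
            if cond_t not in (BOOL, ERROR):
                self.err(f"if condition must be bool, got {cond_t}", s.pos)
            for b in s.then:
                self.check_stmt(b)
            for b in s.orelse:
                self.check_stmt(b)
        elif isinstance(s, Decl):
            try:
                declared = resolve_type(s.var_type)
            except KeyError:
                declared = self.err(f"unknown type {s.var_type!r}", s.pos)
            value_t = self.infer(s.expr)
            if not self._assignable(declared, value_t):
                self.err(f"cannot initialize {declared} variable {s.name!r} with {value_t}", s.pos)
            if s.name in self.env:
                self.err(f"variable {s.name!r} already declared", s.pos)
            if s.name in self.outputs:
                self.err(f"variable {s.name!r} collides with an output", s.pos)
            self.env[s.name] = declared
        elif isinstance(s, Assign):
            if s.name not in self.env:
                self.err(f"assignment to undeclared variable {s.name!r}", s.pos)
                self.infer(s.expr)
                return
            target = self.env[s.name]
            value_t = self.infer(s.expr)
            if not self._assignable(target, value_t):
                self.err(f"cannot assign {value_t} to {target} variable {s.name!r}", s.pos)
        else:
            raise TypeError(f"unknown statement node {s!r}")

    def check_emit(self, s: Emit) -> None:
        decl = self.outputs.get(s.output)
        if decl is None:
            self.err(f"emit to undeclared output {s.output!r}", s.pos)
            for i in s.indices:
                self.infer(i)
            self.infer(s.value)
            if s.weight is not None:
                self.infer(s.weight)
            return
        if len(s.indices) != len(decl.index_types):
            self.err(
                f"output {s.output!r} has {len(decl.index_types)} index(es), "
                f"emit gives {len(s.indices)}", s.pos)
        for i, (idx_expr, idx_type) in enumerate(zip(s.indices, decl.index_types)):
            it = self.infer(idx_expr)
            want = _SCALARS.get(idx_type, ERROR)
            if not self._assignable(want, it) or (want is FLOAT and it is INT):
                if it != want and it is not ERROR:
                    self.err(
                        f"index {i + 1} of output {s.output!r} is {idx_type}, got {it}", s.pos)
        for idx_expr in s.indices[len(decl.index_types):]:
            self.infer(idx_expr)
        vt = self.infer(s.value)
        want_v = _SCALARS.get(decl.value_type, ERROR)
        if not self._assignable(want_v, vt):
            self.err(
                f"output {s.output!r} takes {decl.value_type} values, got {vt}", s.pos)
        if s.weight is not None and decl.weight_type is None:
            self.err(f"output {s.output!r} is not declared with a weight", s.pos)
        elif s.weight is None and decl.weight_type is not None:
            self.err(f"output {s.output!r} requires a weight expression", s.pos)
        if s.weight is not None:
            wt = self.infer(s.weight)
            want_w = _SCALARS.get(decl.weight_type or "float", ERROR)
            if not self._assignable(want_w, wt):
                self.err(
                    f"output {s.output!r} weight is {decl.weight_type}, got {wt}", s.pos)

    def run(self) -> list[TypeError_]:
        for d in self.program.output_decls:
            self.check_output_decl(d)
        for s in self.program.statements:
            self.check_stmt(s)
        return self.errors


def typecheck(program: Program) -> list[TypeError_]:
    """Type-check a parsed program; returns the (possibly empty) error list.

    On success every expression node carries a ``ty`` annotation used by the
    compiler; with a non-empty error list the program must not be compiled.
    """
    return _Checker(program).run()
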