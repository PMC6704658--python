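"""Recursive-descent parser for the query language.

Grammar (EBNF):

    program   := inputdecl decl* stmt*
    inputdecl := IDENT ":" "Genome" "=" "input" ";"
    decl      := IDENT ":" "output" AGG [ "(" INT ")" ] { "[" type "]" }
                 "of" type [ "weight" type ] ";"
    stmt      := "emit" IDENT { "[" expr "]" } "<<" expr [ "weight" expr ] ";"
               | "foreach" "(" IDENT ":" type "in" expr ")" block
               | "if" "(" expr ")" block [ "else" block ]
               | IDENT ":" type "=" expr ";"
               | IDENT "=" expr ";"
    block     := "{" stmt* "}"

Expressions have C-like precedence: ``||`` < ``&&`` < equality <
relational < additive < multiplicative < unary < postfix (field access,
indexing, calls). Aggregator arguments (e.g. ``top(0)``) are accepted here
and validated by the typechecker.
"""

from __future__ import annotations

from typing import Optional

from .lexer import DslSyntaxError, Token, tokenize
from .nodes import (
    Assign, Binary, BoolLit, Call, Decl, Emit, Expr, FieldAccess, FloatLit,
    Foreach, IfStmt, IndexExpr, IntLit, OutputDecl, Pos, Program, Stmt,
    StringLit, Unary, Var,
)

__all__ = ["parse", "parse_source"]

AGG_KINDS = ("sum", "mean", "maximum", "minimum", "top", "stdev")

TYPE_NAMES = frozenset({
    "int", "float", "string", "bool",
    "Genome", "Sequence", "Feature", "Attribute", "Assembler", "Assembly",
})


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def error(self, message: str, tok: Optional[Token] = None) -> DslSyntaxError:
        tok = tok or self.cur
        return DslSyntaxError(message, tok.line, tok.col)

    def at(self, kind: str) -> bool:
        return self.cur.kind == kind

    def accept(self, kind: str) -> Optional[Token]:
        if self.at(kind):
            tok = self.cur
            self.i += 1
            return tok
        return None

    def expect(self, kind: str, what: str = "") -> Token:
        tok = self.accept(kind)
        if tok is None:
            shown = self.cur.text or self.cur.kind
            raise self.error(f"expected {what or kind!r}, found {shown!r}")
        return tok

    def pos(self, tok: Token) -> Pos:
        return Pos(tok.line, tok.col)

    # -- program ------------------------------------------------------------

    def parse_program(self) -> Program:
        head = self.expect("IDENT", "input variable name")
        self.expect(":")
        gtok = self.expect("IDENT", "'Genome'")
        if gtok.text != "Genome":
            raise self.error("input binding must have type Genome", gtok)
        self.expect("=")
        self.expect("input", "'input'")
        self.expect(";")
        decls: list[OutputDecl] = []
        while self._looks_like_output_decl():
            decls.append(self.parse_output_decl())
        stmts: list[Stmt] = []
        while not self.at("EOF"):
            stmts.append(self.parse_stmt())
        return Program(input_var=head.text, output_decls=decls,
                       statements=stmts, pos=self.pos(head))

    def _looks_like_output_decl(self) -> bool:
        return (self.at("IDENT")
                and self.tokens[self.i + 1].kind == ":"
                and self.tokens[self.i + 2].kind == "output")

    def parse_type_name(self) -> str:
        tok = self.expect("IDENT", "type name")
        if tok.text not in TYPE_NAMES:
            raise self.error(f"unknown type name {tok.text!r}", tok)
        return tok.text

    def parse_output_decl(self) -> OutputDecl:
        name = self.expect("IDENT")
        self.expect(":")
        self.expect("output", "'output'")
        agg = self.expect("IDENT", "aggregator kind")
        if agg.text not in AGG_KINDS:
            raise self.error(
                f"unknown aggregator {agg.text!r} (expected one of {', '.join(AGG_KINDS)})", agg)
        agg_arg: Optional[int] = None
        if self.accept("("):
            arg = self.expect("INT", "integer aggregator argument")
            agg_arg = int(arg.text)
            self.expect(")")
        index_types: list[str] = []
        while self.accept("["):
            index_types.append(self.parse_type_name())
            self.expect("]")
        self.expect("of", "'of'")
        value_type = self.parse_type_name()
        weight_type: Optional[str] = None
        if self.accept("weight"):
            weight_type = self.parse_type_name()
        self.expect(";")
        return OutputDecl(name=name.text, agg_kind=agg.text, agg_arg=agg_arg,
                          index_types=index_types, value_type=value_type,
                          weight_type=weight_type, pos=self.pos(name))

    # -- statements ----------------------------------------------------------

    def parse_block(self) -> list[Stmt]:
        self.expect("{")
        stmts: list[Stmt] = []
        while not self.accept("}"):
            if self.at("EOF"):
                raise self.error("expected '}' before end of input")
            stmts.append(self.parse_stmt())
        return stmts

    def parse_stmt(self) -> Stmt:
        if self.at("emit"):
            return self.parse_emit()
        if self.at("foreach"):
            return self.parse_foreach()
        if self.at("if"):
            return self.parse_if()
        if self.at("IDENT"):
            name = self.cur
            nxt = self.tokens[self.i + 1].kind
            if nxt == ":":
                self.i += 2
                var_type = self.parse_type_name()
                self.expect("=")
                expr = self.parse_expr()
                self.expect(";")
                return Decl(name=name.text, var_type=var_type, expr=expr,
                            pos=self.pos(name))
            if nxt == "=":
                self.i += 2
                expr = self.parse_expr()
                self.expect(";")
                return Assign(name=name.text, expr=expr, pos=self.pos(name))
        shown = self.cur.text or self.cur.kind
        raise self.error(f"expected a statement, found {shown!r}")

    def parse_emit(self) -> Emit:
        head = self.expect("emit")
        output = self.expect("IDENT", "output name")
        indices: list[Expr] = []
        while self.accept("["):
            indices.append(self.parse_expr())
            self.expect("]")
        self.expect("<<", "'<<'")
        value = self.parse_expr()
        weight: Optional[Expr] = None
        if self.accept("weight"):
            weight = self.parse_expr()
        self.expect(";")
        return Emit(output=output.text, indices=indices, value=value,
                    weight=weight, pos=self.pos(head))

    def parse_foreach(self) -> Foreach:
        head = self.expect("foreach")
        self.expect("(")
        var = self.expect("IDENT", "loop variable")
        self.expect(":")
        var_type = self.parse_type_name()
        self.expect("in", "'in'")
        iterable = self.parse_expr()
        self.expect(")")
        body = self.parse_block()
        return Foreach(var=var.text, var_type=var_type, iterable=iterable,
                       body=body, pos=self.pos(head))

    def parse_if(self) -> IfStmt:
        head = self.expect("if")
        self.expect("(")
        cond = self.parse_expr()
        self.expect(")")
        then = self.parse_block()
        orelse: list[Stmt] = []
        if self.accept("else"):
            orelse = self.parse_block()
        return IfStmt(cond=cond, then=then, orelse=orelse, pos=self.pos(head))

    # -- expressions ---------------------------------------------------------

    def parse_expr(self) -> Expr:
        return self.parse_or()

    def _binary_chain(self, sub, ops) -> Expr:
        left = sub()
        while self.cur.kind in ops:
            op = self.cur
            self.i += 1
            right = sub()
            left = Binary(op=op.kind, left=left, right=right, pos=self.pos(op))
        return left

    def parse_or(self) -> Expr:
        return self._binary_chain(self.parse_and, ("||",))

    def parse_and(self) -> Expr:
        return self._binary_chain(self.parse_equality, ("&&",))

    def parse_equality(self) -> Expr:
        return self._binary_chain(self.parse_relational, ("==", "!="))

    def parse_relational(self) -> Expr:
        return self._binary_chain(self.parse_additive, ("<", "<=", ">", ">="))

    def parse_additive(self) -> Expr:
        return self._binary_chain(self.parse_multiplicative, ("+", "-"))

    def parse_multiplicative(self) -> Expr:
        return self._binary_chain(self.parse_unary, ("*", "/", "%"))

    def parse_unary(self) -> Expr:
        if self.cur.kind in ("-", "!"):
            op = self.cur
            self.i += 1
            return Unary(op=op.kind, operand=self.parse_unary(), pos=self.pos(op))
        return self.parse_postfix()

    def parse_postfix(self) -> Expr:
        expr = self.parse_primary()
        while True:
            if self.accept("."):
                name = self.expect("IDENT", "field name")
                expr = FieldAccess(obj=expr, name=name.text, pos=self.pos(name))
            elif self.accept("["):
                index = self.parse_expr()
                self.expect("]")
                expr = IndexExpr(obj=expr, index=index)
            else:
                return expr

    def parse_primary(self) -> Expr:
        tok = self.cur
        if self.accept("INT"):
            return IntLit(value=int(tok.text), pos=self.pos(tok))
        if self.accept("FLOAT"):
            return FloatLit(value=float(tok.text), pos=self.pos(tok))
        if self.accept("STRING"):
            return StringLit(value=tok.text, pos=self.pos(tok))
        if self.accept("true"):
            return BoolLit(value=True, pos=self.pos(tok))
        if self.accept("false"):
            return BoolLit(value=False, pos=self.pos(tok))
        if self.accept("("):
            expr = self.parse_expr()
            self.expect(")")
            return expr
        if self.accept("IDENT"):
            if self.accept("("):
                args: list[Expr] = []
                if not self.at(")"):
                    args.append(self.parse_expr())
                    while self.accept(","):
                        args.append(self.parse_expr())
                self.expect(")")
                return Call(name=tok.text, args=args, pos=self.pos(tok))
            return Var(name=tok.text, pos=self.pos(tok))
        shown = tok.text or tok.kind
        raise self.error(f"expected an expression, found {shown!r}")


def parse(tokens: list[Token]) -> Program:
    """Parse a token list into a Program; raises DslSyntaxError on failure."""
    parser = _Parser(tokens)
    program = parser.parse_program()
    parser.expect("EOF")
    return program


def parse_source(source: str) -> Program:
    """Convenience: tokenize + parse."""
    return parse(tokenize(source))
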