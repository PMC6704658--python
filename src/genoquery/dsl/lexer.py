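"""Tokenizer for the query language.

Produces a flat token list with line/column positions. ``#`` starts a
comment running to end of line. Keywords are lexed as their own token
kinds; type names (int, Genome, ...) are plain identifiers resolved by the
parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Token", "DslSyntaxError", "tokenize", "KEYWORDS"]

KEYWORDS = frozenset({
    "output", "of", "weight", "input", "emit", "foreach", "in",
    "if", "else", "true", "false",
})

_TWO_CHAR = ("<<", "==", "!=", "<=", ">=", "&&", "||")
_ONE_CHAR = set("+-*/%<>=!(){}[]:;,.")


class DslSyntaxError(ValueError):
    """Lexical or syntax error with source position."""

    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{line}:{col}: {message}")
        self.line = line
        self.col = col


@dataclass(frozen=True)
class Token:
    """kind is 'IDENT', 'INT', 'FLOAT', 'STRING', 'EOF', a keyword, or a symbol."""

    kind: str
    text: str
    line: int = field(compare=False, default=0)
    col: int = field(compare=False, default=0)


def tokenize(source: str) -> list[Token]:
    """Tokenize source text; raises DslSyntaxError on an illegal character."""
    tokens: list[Token] = []
    i = 0
    line = 1
    col = 1
    n = len(source)

    def advance(k: int) -> None:
        nonlocal i, line, col
        for _ in range(k):
            if source[i] == "\n":
                line += 1
                col = 1
            else:
                col += 1
            i += 1

    while i < n:
        ch = source[i]
        if ch in " \t\r\n":
            advance(1)
            continue
        if ch == "#":
            while i < n and source[i] != "\n":
                advance(1)
            continue
        tline, tcol = line, col
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            word = source[i:j]
            kind = word if word in KEYWORDS else "IDENT"
            tokens.append(Token(kind, word, tline, tcol))
            advance(j - i)
            continue
        if ch.isdigit():
            j = i
            while j < n and source[j].isdigit():
                j += 1
            is_float = False
            if j < n and source[j] == "." and j + 1 < n and source[j + 1].isdigit():
                is_float = True
                j += 1
                while j < n and source[j].isdigit():
                    j += 1
            if j < n and source[j] in "eE":
                k = j + 1
                if k < n and source[k] in "+-":
                    k += 1
                if k < n and source[k].isdigit():
                    is_float = True
                    j = k
                    while j < n and source[j].isdigit():
                        j += 1
            tokens.append(Token("FLOAT" if is_float else "INT", source[i:j], tline, tcol))
            advance(j - i)
            continue
        if ch == '"':
            j = i + 1
            chars: list[str] = []
            while True:
                if j >= n or source[j] == "\n":
                    raise DslSyntaxError("unterminated string literal", tline, tcol)
                c = source[j]
                if c == '"':
                    j += 1
                    break
                if c == "\\":
                    if j + 1 >= n:
                        raise DslSyntaxError("unterminated escape", tline, tcol)
                    esc = source[j + 1]
                    chars.append({"n": "\n", "t": "\t", '"': '"', "\\": "\\"}.get(esc, esc))
                    j += 2
                else:
                    chars.append(c)
                    j += 1
            tokens.append(Token("STRING", "".join(chars), tline, tcol))
            advance(j - i)
            continue
        two = source[i:i + 2]
        if two in _TWO_CHAR:
            tokens.append(Token(two, two, tline, tcol))
            advance(2)
            continue
        if ch in _ONE_CHAR:
            tokens.append(Token(ch, ch, tline, tcol))
            advance(1)
            continue
        raise DslSyntaxError(f"illegal character {ch!r}", tline, tcol)
    tokens.append(Token("EOF", "", line, col))
    return tokens
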