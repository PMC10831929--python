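"""Parsing and evaluation of Boolean logic rules and arithmetic rate formulas.

Two small grammars are used throughout the model dialect:

* Boolean rules over node names, e.g. ``Prol_KC AND STAT3`` or
  ``!(IL10 | TGFb)``.  Keywords ``AND``/``OR``/``NOT`` are case-insensitive
  and the symbolic forms ``&``, ``|``, ``!`` (plus ``&&``/``||``) are
  accepted interchangeably.
* Arithmetic rate formulas over numeric literals, ``$parameter`` symbols,
  node probabilities ``p[Node]`` and the special variable ``pop_ratio``,
  e.g. ``$c_IL10R * p[IL10]`` — used for rate constants and for the
  per-step receptor-rate update rules of the population layer.

ASTs are plain nested tuples so they are hashable and trivially comparable:

Boolean:    ``("const", 0|1) | ("var", name) | ("not", x) |
            ("and", a, b) | ("or", a, b)``
Arithmetic: ``("num", float) | ("param", name) | ("prob", node) |
            ("popratio",) | ("neg", x) | ("add"|"sub"|"mul"|"div", a, b)``
"""

from __future__ import annotations

import re

__all__ = [
    "ParseError",
    "parse_bool",
    "parse_arith",
    "bool_eval",
    "bool_regulators",
    "bool_to_str",
    "arith_eval",
    "arith_params",
    "arith_probs",
    "arith_to_str",
]


class ParseError(ValueError):
    """Syntax or reference error in a model expression, with a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>[ \t\r\n]+)
  | (?P<num>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
  | (?P<param>\$[A-Za-z_]\w*)
  | (?P<name>[A-Za-z_]\w*)
  | (?P<sym>&&|\|\||[-+*/()&|!\[\]])
    """,
    re.VERBOSE,
)


def _tokenize(text: str, line: int | None = None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r} in {text.strip()!r}", line)
        pos = m.end()
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group()))
    return tokens


class _Parser:
    def __init__(self, text: str, line: int | None):
        self.tokens = _tokenize(text, line)
        self.text = text
        self.line = line
        self.i = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def advance(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ParseError(f"unexpected end of expression in {self.text.strip()!r}", self.line)
        self.i += 1
        return tok

    def expect_sym(self, sym: str) -> None:
        tok = self.peek()
        if tok is None or tok != ("sym", sym):
            got = tok[1] if tok else "end of expression"
            raise ParseError(f"expected {sym!r}, got {got!r} in {self.text.strip()!r}", self.line)
        self.i += 1

    def done(self) -> None:
        tok = self.peek()
        if tok is not None:
            raise ParseError(
                f"trailing input {tok[1]!r} in {self.text.strip()!r}", self.line
            )


# --------------------------------------------------------------------------
# Boolean rules
# --------------------------------------------------------------------------

_BOOL_KEYWORDS = {"and", "or", "not", "true", "false"}


def parse_bool(text: str, line: int | None = None):
    """Parse a Boolean rule into an AST tuple."""
    p = _Parser(text, line)
    ast = _bool_or(p)
    p.done()
    return ast


def _is_kw(tok, kw: str) -> bool:
    return tok is not None and tok[0] == "name" and tok[1].lower() == kw


def _bool_or(p: _Parser):
    left = _bool_and(p)
    while True:
        tok = p.peek()
        if tok in (("sym", "|"), ("sym", "||")) or _is_kw(tok, "or"):
            p.advance()
            left = ("or", left, _bool_and(p))
        else:
            return left


def _bool_and(p: _Parser):
    left = _bool_not(p)
    while True:
        tok = p.peek()
        if tok in (("sym", "&"), ("sym", "&&")) or _is_kw(tok, "and"):
            p.advance()
            left = ("and", left, _bool_not(p))
        else:
            return left


def _bool_not(p: _Parser):
    tok = p.peek()
    if tok == ("sym", "!") or _is_kw(tok, "not"):
        p.advance()
        return ("not", _bool_not(p))
    return _bool_atom(p)


def _bool_atom(p: _Parser):
    tok = p.advance()
    kind, val = tok
    if kind == "name":
        low = val.lower()
        if low == "true":
            return ("const", 1)
        if low == "false":
            return ("const", 0)
        if low in _BOOL_KEYWORDS:
            raise ParseError(f"misplaced keyword {val!r} in {p.text.strip()!r}", p.line)
        return ("var", val)
    if kind == "num":
        if val in ("0", "1"):
            return ("const", int(val))
        raise ParseError(f"numeric literal {val!r} is not a Boolean constant", p.line)
    if tok == ("sym", "("):
        inner = _bool_or(p)
        p.expect_sym(")")
        return inner
    raise ParseError(f"unexpected token {val!r} in rule {p.text.strip()!r}", p.line)


def bool_eval(ast, env) -> int:
    """Evaluate a Boolean AST under ``env`` mapping node name -> 0/1."""
    op = ast[0]
    if op == "const":
        return ast[1]
    if op == "var":
        return 1 if env[ast[1]] else 0
    if op == "not":
        return 1 - bool_eval(ast[1], env)
    if op == "and":
        return bool_eval(ast[1], env) & bool_eval(ast[2], env)
    if op == "or":
        return bool_eval(ast[1], env) | bool_eval(ast[2], env)
    raise ValueError(f"bad boolean AST node {op!r}")


def bool_regulators(ast) -> dict[str, set[int]]:
    """Regulators of a rule with their syntactic polarity.

    Returns ``{node: signs}`` where signs is a subset of ``{+1, -1}``;
    a node under an odd number of NOTs contributes -1.  A regulator can
    appear with both polarities (dual-sign regulation is surfaced, not
    collapsed).
    """
    out: dict[str, set[int]] = {}

    def walk(node, sign):
        op = node[0]
        if op == "var":
            out.setdefault(node[1], set()).add(sign)
        elif op == "not":
            walk(node[1], -sign)
        elif op in ("and", "or"):
            walk(node[1], sign)
            walk(node[2], sign)

    walk(ast, 1)
    return out


def bool_to_str(ast) -> str:
    """Serialize a Boolean AST back to rule text (parseable round trip)."""

    def go(node, parent_prec):
        op = node[0]
        if op == "const":
            return "TRUE" if node[1] else "FALSE"
        if op == "var":
            return node[1]
        if op == "not":
            return "NOT " + go(node[1], 3)
        prec = 2 if op == "and" else 1
        kw = " AND " if op == "and" else " OR "
        # parse is left-associative: right operand needs parens at equal prec
        s = go(node[1], prec) + kw + go(node[2], prec + 1)
        if prec < parent_prec:
            s = "(" + s + ")"
        return s

    return go(ast, 0)


# --------------------------------------------------------------------------
# Arithmetic rate formulas
# --------------------------------------------------------------------------


def parse_arith(text: str, line: int | None = None):
    """Parse an arithmetic rate formula into an AST tuple."""
    p = _Parser(text, line)
    ast = _arith_sum(p)
    p.done()
    return ast


def _arith_sum(p: _Parser):
    left = _arith_term(p)
    while True:
        tok = p.peek()
        if tok == ("sym", "+"):
            p.advance()
            left = ("add", left, _arith_term(p))
        elif tok == ("sym", "-"):
            p.advance()
            left = ("sub", left, _arith_term(p))
        else:
            return left


def _arith_term(p: _Parser):
    left = _arith_factor(p)
    while True:
        tok = p.peek()
        if tok == ("sym", "*"):
            p.advance()
            left = ("mul", left, _arith_factor(p))
        elif tok == ("sym", "/"):
            p.advance()
            left = ("div", left, _arith_factor(p))
        else:
            return left


def _arith_factor(p: _Parser):
    tok = p.peek()
    if tok == ("sym", "-"):
        p.advance()
        return ("neg", _arith_factor(p))
    return _arith_atom(p)


def _arith_atom(p: _Parser):
    tok = p.advance()
    kind, val = tok
    if kind == "num":
        return ("num", float(val))
    if kind == "param":
        return ("param", val[1:])
    if kind == "name":
        if val == "pop_ratio":
            return ("popratio",)
        if val == "p":
            p.expect_sym("[")
            ntok = p.advance()
            if ntok[0] != "name":
                raise ParseError(f"expected node name inside p[...], got {ntok[1]!r}", p.line)
            p.expect_sym("]")
            return ("prob", ntok[1])
        raise ParseError(
            f"bare identifier {val!r} in rate formula (use $param, p[Node] or pop_ratio)",
            p.line,
        )
    if tok == ("sym", "("):
        inner = _arith_sum(p)
        p.expect_sym(")")
        return inner
    raise ParseError(f"unexpected token {val!r} in formula {p.text.strip()!r}", p.line)


def arith_eval(ast, params, probs=None, pop_ratio=None) -> float:
    op = ast[0]
    if op == "num":
        return ast[1]
    if op == "param":
        try:
            return float(params[ast[1]])
        except KeyError:
            raise ParseError(f"unbound parameter ${ast[1]}") from None
    if op == "prob":
        if probs is None:
            raise ParseError(f"node probability p[{ast[1]}] not available in this context")
        try:
            return float(probs[ast[1]])
        except KeyError:
            raise ParseError(f"unknown node {ast[1]!r} in formula") from None
    if op == "popratio":
        if pop_ratio is None:
            raise ParseError("pop_ratio not available in this context")
        return float(pop_ratio)
    if op == "neg":
        return -arith_eval(ast[1], params, probs, pop_ratio)
    a = arith_eval(ast[1], params, probs, pop_ratio)
    b = arith_eval(ast[2], params, probs, pop_ratio)
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    if op == "div":
        return a / b
    raise ValueError(f"bad arithmetic AST node {op!r}")


def _collect(ast, kind: str, out: set[str]) -> None:
    if ast[0] == kind:
        out.add(ast[1])
    for child in ast[1:]:
        if isinstance(child, tuple):
            _collect(child, kind, out)


def arith_params(ast) -> set[str]:
    """Parameter symbols referenced by a formula."""
    out: set[str] = set()
    _collect(ast, "param", out)
    return out


def arith_probs(ast) -> set[str]:
    """Node names whose probability a formula references."""
    out: set[str] = set()
    _collect(ast, "prob", out)
    return out


def arith_to_str(ast) -> str:
    op = ast[0]
    if op == "num":
        v = ast[1]
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if op == "param":
        return "$" + ast[1]
    if op == "prob":
        return f"p[{ast[1]}]"
    if op == "popratio":
        return "pop_ratio"
    if op == "neg":
        return "-" + _paren(ast[1], 3)
    sym = {"add": " + ", "sub": " - ", "mul": " * ", "div": " / "}[op]
    prec = 1 if op in ("add", "sub") else 2
    left = _paren(ast[1], prec)
    # parse is left-associative: right operand needs parens at equal prec
    right = _paren(ast[2], prec + 1)
    return left + sym + right


def _paren(ast, parent_prec: int) -> str:
    prec = {"add": 1, "sub": 1, "mul": 2, "div": 2}.get(ast[0], 4)
    s = arith_to_str(ast)
    return "(" + s + ")" if prec < parent_prec else s
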