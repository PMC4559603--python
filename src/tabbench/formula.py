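"""Excel-style formula language for calculated columns.

Formulas reference table columns by name (bare identifiers, or
``[bracketed names]`` when the name contains spaces) instead of cell
addresses, and evaluate row-wise: ``=LOG2(ko+1)-LOG2(wt+1)`` produces one
value per row. Supported operators are ``+ - * / ^`` and the comparisons
``= <> < <= > >=`` (yielding 1/0); ``^`` is right-associative and binds
tighter than unary minus, everything else is left-associative.

Error policy is missing-value propagation: division by zero, log of a
non-positive number and sqrt of a negative all produce a missing value
(NaN), and missing propagates through arithmetic. This keeps calculated
columns numeric instead of introducing Excel's ``#DIV/0!`` style sentinels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import FormulaError, SchemaError

FUNCTIONS = {
    "ABS", "LOG", "LOG2", "LOG10", "SQRT", "EXP",
    "MIN", "MAX", "MEAN", "SUM",
    "IF", "AND", "OR", "NOT", "ROUND",
}

# arity: (min, max); None = unbounded
_ARITY = {
    "ABS": (1, 1), "LOG": (1, 2), "LOG2": (1, 1), "LOG10": (1, 1),
    "SQRT": (1, 1), "EXP": (1, 1),
    "MIN": (1, None), "MAX": (1, None), "MEAN": (1, None), "SUM": (1, None),
    "IF": (3, 3), "AND": (1, None), "OR": (1, None), "NOT": (1, 1),
    "ROUND": (1, 2),
}


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Str:
    value: str


@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class Unary:
    op: str  # "-"
    operand: "Node"


@dataclass(frozen=True)
class BinOp:
    op: str
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Func:
    name: str
    args: tuple["Node", ...]


Node = Union[Num, Str, Ref, Unary, BinOp, Func]

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


def referenced_columns(node: Node) -> list[str]:
    """Column names referenced by a formula, in first-appearance order."""
    seen: dict[str, None] = {}

    def walk(n: Node) -> None:
        if isinstance(n, Ref):
            seen.setdefault(n.name)
        elif isinstance(n, Unary):
            walk(n.operand)
        elif isinstance(n, BinOp):
            walk(n.left)
            walk(n.right)
        elif isinstance(n, Func):
            for a in n.args:
                walk(a)

    walk(node)
    return list(seen)


def serialize_formula(node: Node) -> str:
    """Render an AST back to formula text (fully parenthesized, lossless)."""
    if isinstance(node, Num):
        # negative literals get parens so "^" cannot re-bind them on re-parse
        return f"({node.value!r})" if node.value < 0 else repr(node.value)
    if isinstance(node, Str):
        return '"' + node.value + '"'
    if isinstance(node, Ref):
        return node.name if _IDENT_RE.match(node.name) else f"[{node.name}]"
    if isinstance(node, Unary):
        return f"(-{serialize_formula(node.operand)})"
    if isinstance(node, BinOp):
        return f"({serialize_formula(node.left)}{node.op}{serialize_formula(node.right)})"
    if isinstance(node, Func):
        return node.name + "(" + ",".join(serialize_formula(a) for a in node.args) + ")"
    raise TypeError(f"not a formula node: {node!r}")


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # num str ident bracket op lparen rparen comma end
    text: str
    pos: int


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
  | (?P<str>"[^"]*")
  | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
  | (?P<bracket>\[[^\]]+\])
  | (?P<op><=|>=|<>|[+\-*/^=<>])
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<comma>,)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    tokens.append(_Token("end", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent; precedence ^ > unary- > * / > + - > comparisons)


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.cur
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        if self.cur.kind != kind:
            raise FormulaError(f"expected {what}", self.cur.pos)
        return self.advance()

    def parse(self) -> Node:
        node = self.comparison()
        if self.cur.kind != "end":
            raise FormulaError(f"unexpected token {self.cur.text!r}", self.cur.pos)
        return node

    def comparison(self) -> Node:
        node = self.additive()
        while self.cur.kind == "op" and self.cur.text in ("=", "<>", "<", "<=", ">", ">="):
            op = self.advance().text
            node = BinOp(op, node, self.additive())
        return node

    def additive(self) -> Node:
        node = self.term()
        while self.cur.kind == "op" and self.cur.text in ("+", "-"):
            op = self.advance().text
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.cur.kind == "op" and self.cur.text in ("*", "/"):
            op = self.advance().text
            node = BinOp(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.cur.kind == "op" and self.cur.text == "-":
            self.advance()
            return Unary("-", self.unary())
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        if self.cur.kind == "op" and self.cur.text == "^":
            self.advance()
            return BinOp("^", base, self.unary())  # right-assoc; exponent may be signed
        return base

    def atom(self) -> Node:
        tok = self.cur
        if tok.kind == "num":
            self.advance()
            return Num(float(tok.text))
        if tok.kind == "str":
            self.advance()
            return Str(tok.text[1:-1])
        if tok.kind == "bracket":
            self.advance()
            return Ref(tok.text[1:-1].strip())
        if tok.kind == "lparen":
            self.advance()
            node = self.comparison()
            self.expect("rparen", "')'")
            return node
        if tok.kind == "ident":
            self.advance()
            if self.cur.kind == "lparen":
                return self.call(tok)
            return Ref(tok.text)
        raise FormulaError(f"unexpected token {tok.text or 'end of formula'!r}", tok.pos)

    def call(self, name_tok: _Token) -> Node:
        fname = name_tok.text.upper()
        if fname not in FUNCTIONS:
            raise FormulaError(f"unknown function {name_tok.text!r}", name_tok.pos)
        self.expect("lparen", "'('")
        args: list[Node] = []
        if self.cur.kind != "rparen":
            args.append(self.comparison())
            while self.cur.kind == "comma":
                self.advance()
                args.append(self.comparison())
        self.expect("rparen", "')'")
        lo, hi = _ARITY[fname]
        if len(args) < lo or (hi is not None and len(args) > hi):
            raise FormulaError(
                f"{fname} takes {lo}{'' if hi == lo else ('+' if hi is None else f'-{hi}')}"
                f" argument(s), got {len(args)}",
                name_tok.pos,
            )
        return Func(fname, tuple(args))


def parse_formula(text: str) -> Node:
    """Parse formula text (optional leading ``=``) into an AST."""
    if not text or not text.strip():
        raise FormulaError("empty formula")
    stripped = text.strip()
    if stripped.startswith("="):
        stripped = stripped[1:]
    if not stripped.strip():
        raise FormulaError("empty formula after '='")
    return _Parser(_tokenize(stripped)).parse()


# ---------------------------------------------------------------------------
# Evaluator (vectorized; one value per table row)


def _numeric(x, n: int) -> np.ndarray:
    if isinstance(x, np.ndarray) and x.dtype == object:
        raise FormulaError("text value used where a number is required")
    return np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()


def _apply_binop(op: str, left, right, n: int):
    if op in ("=", "<>") and (
        (isinstance(left, np.ndarray) and left.dtype == object)
        or (isinstance(right, np.ndarray) and right.dtype == object)
    ):
        l = np.broadcast_to(np.asarray(left, dtype=object), (n,))
        r = np.broadcast_to(np.asarray(right, dtype=object), (n,))
        eq = np.asarray([a == b for a, b in zip(l, r)], dtype=float)
        return eq if op == "=" else 1.0 - eq
    l, r = _numeric(left, n), _numeric(right, n)
    with np.errstate(all="ignore"):
        if op == "+":
            return l + r
        if op == "-":
            return l - r
        if op == "*":
            return l * r
        if op == "/":
            out = l / r
            out[r == 0] = np.nan
            return out
        if op == "^":
            out = np.power(l, r)
            out[~np.isfinite(out)] = np.nan
            return out
        nan = np.isnan(l) | np.isnan(r)
        if op == "=":
            out = (l == r).astype(float)
        elif op == "<>":
            out = (l != r).astype(float)
        elif op == "<":
            out = (l < r).astype(float)
        elif op == "<=":
            out = (l <= r).astype(float)
        elif op == ">":
            out = (l > r).astype(float)
        elif op == ">=":
            out = (l >= r).astype(float)
        else:  # pragma: no cover
            raise FormulaError(f"unknown operator {op!r}")
        out[nan] = np.nan
        return out


def _guarded_log(arr: np.ndarray, base: np.ndarray | None = None) -> np.ndarray:
    with np.errstate(all="ignore"):
        out = np.log10(arr) if base is None else np.log(arr) / np.log(base)
    out[~(arr > 0)] = np.nan
    return out


def _round_half_away(arr: np.ndarray, digits: np.ndarray) -> np.ndarray:
    scale = np.power(10.0, digits)
    with np.errstate(all="ignore"):
        return np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale


def _apply_func(name: str, args: list, n: int) -> np.ndarray:
    if name == "IF":
        cond = _numeric(args[0], n)
        then = _numeric(args[1], n)
        other = _numeric(args[2], n)
        out = np.where(cond != 0, then, other)
        out[np.isnan(cond)] = np.nan
        return out
    vecs = [_numeric(a, n) for a in args]
    with np.errstate(all="ignore"):
        if name == "ABS":
            return np.abs(vecs[0])
        if name == "SQRT":
            out = np.sqrt(vecs[0])
            out[vecs[0] < 0] = np.nan
            return out
        if name == "EXP":
            return np.exp(vecs[0])
        if name == "LOG":
            return _guarded_log(vecs[0], vecs[1] if len(vecs) == 2 else None)
        if name == "LOG2":
            out = np.log2(vecs[0])
            out[~(vecs[0] > 0)] = np.nan
            return out
        if name == "LOG10":
            return _guarded_log(vecs[0])
        if name == "ROUND":
            digits = vecs[1] if len(vecs) == 2 else np.zeros(n)
            return _round_half_away(vecs[0], digits)
        stack = np.vstack(vecs)
        if name == "MIN":
            return stack.min(axis=0)
        if name == "MAX":
            return stack.max(axis=0)
        if name == "SUM":
            return stack.sum(axis=0)
        if name == "MEAN":
            return stack.mean(axis=0)
        nan = np.isnan(stack).any(axis=0)
        if name == "AND":
            out = np.all(stack != 0, axis=0).astype(float)
        elif name == "OR":
            out = np.any(np.nan_to_num(stack) != 0, axis=0).astype(float)
        elif name == "NOT":
            out = (stack[0] == 0).astype(float)
        else:  # pragma: no cover
            raise FormulaError(f"unknown function {name!r}")
        out[nan] = np.nan
        return out


def evaluate_formula(node: Node, table) -> np.ndarray:
    """Evaluate an AST over a table, returning one value per row.

    Column references are checked before evaluation; a reference to an
    absent column raises :class:`SchemaError`. Aggregate names (MIN, MAX,
    MEAN, SUM) operate across their arguments within each row, never down
    a column.
    """
    n = table.n
    for name in referenced_columns(node):
        if name not in table:
            raise SchemaError(f"formula references unknown column {name!r}")

    def ev(nd: Node):
        if isinstance(nd, Num):
            return np.full(n, nd.value)
        if isinstance(nd, Str):
            return np.full(n, nd.value, dtype=object)
        if isinstance(nd, Ref):
            values = table.column_values(nd.name)
            if table.is_numeric(nd.name):
                return np.asarray(values, dtype=float)
            return np.asarray(values, dtype=object)
        if isinstance(nd, Unary):
            return -_numeric(ev(nd.operand), n)
        if isinstance(nd, BinOp):
            return _apply_binop(nd.op, ev(nd.left), ev(nd.right), n)
        if isinstance(nd, Func):
            return _apply_func(nd.name, [ev(a) for a in nd.args], n)
        raise TypeError(f"not a formula node: {nd!r}")

    result = ev(node)
    if isinstance(result, np.ndarray) and result.dtype == object:
        return result
    return _numeric(result, n)


def calculate(table, text: str) -> np.ndarray:
    """Parse and evaluate in one step."""
    return evaluate_formula(parse_formula(text), table)
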