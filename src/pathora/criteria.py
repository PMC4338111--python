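"""Boolean criterion expressions over dataset columns.

A criterion selects the "positive" rows of a dataset — e.g. the
differentially expressed genes::

    ABS([log2FC]) > 1 AND [pvalue] < 0.05

Grammar (precedence low to high: OR < AND < NOT < comparison)::

    expr        := and_expr (OR and_expr)*
    and_expr    := not_expr (AND not_expr)*
    not_expr    := NOT not_expr | primary
    primary     := '(' expr ')' | comparison
    comparison  := value op value         op in < <= > >= = <>
    value       := NUMBER | STRING | '[' column ']' | ABS '(' value ')'

Keywords are case-insensitive; column names are bracketed and may contain
spaces; string literals are single- or double-quoted; numbers use a decimal
point with optional scientific notation (no locale separators). ABS is the
only built-in function.

Evaluation is three-valued (Kleene logic): any comparison touching a
missing value is *undefined* (returned as ``None``), ``NOT`` maps undefined
to undefined, ``AND``/``OR`` short-circuit it away only when the other
operand decides the result. A row counts as meeting a criterion only when
evaluation returns exactly ``True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Set, Union

from .errors import CriterionSyntaxError, CriterionTypeError

__all__ = [
    "Criterion",
    "parse_criterion",
    "evaluate_criterion",
    "ColumnRef",
    "NumberLit",
    "StringLit",
    "Abs",
    "Cmp",
    "And",
    "Or",
    "Not",
    "MISSING",
]

#: Sentinel for a missing cell value (tri-state "undefined" is ``None``).
MISSING = None

_CMP_OPS = ("<=", ">=", "<>", "<", ">", "=")


# ---------------------------------------------------------------------------
# AST

@dataclass(frozen=True)
class ColumnRef:
    name: str


@dataclass(frozen=True)
class NumberLit:
    value: float


@dataclass(frozen=True)
class StringLit:
    value: str


@dataclass(frozen=True)
class Abs:
    arg: "ValueNode"


ValueNode = Union[ColumnRef, NumberLit, StringLit, Abs]


@dataclass(frozen=True)
class Cmp:
    op: str
    left: ValueNode
    right: ValueNode


@dataclass(frozen=True)
class And:
    left: "BoolNode"
    right: "BoolNode"


@dataclass(frozen=True)
class Or:
    left: "BoolNode"
    right: "BoolNode"


@dataclass(frozen=True)
class Not:
    operand: "BoolNode"


BoolNode = Union[Cmp, And, Or, Not]


@dataclass(frozen=True)
class Criterion:
    """A parsed criterion: original text plus its expression tree."""

    source_text: str
    ast: BoolNode

    def column_names(self) -> Set[str]:
        return _columns_of(self.ast)

    def check_columns(self, declared) -> None:
        """Raise if the criterion references a column not in ``declared``."""
        unknown = sorted(self.column_names() - set(declared))
        if unknown:
            raise CriterionTypeError(
                f"criterion references undeclared column(s): {', '.join(unknown)}"
            )

    def pretty(self) -> str:
        return _pretty_bool(self.ast)


def _columns_of(node) -> Set[str]:
    if isinstance(node, ColumnRef):
        return {node.name}
    if isinstance(node, (NumberLit, StringLit)):
        return set()
    if isinstance(node, Abs):
        return _columns_of(node.arg)
    if isinstance(node, Cmp):
        return _columns_of(node.left) | _columns_of(node.right)
    if isinstance(node, Not):
        return _columns_of(node.operand)
    return _columns_of(node.left) | _columns_of(node.right)


# ---------------------------------------------------------------------------
# lexer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<column>\[[^\]]*\])
  | (?P<string>"[^"]*"|'[^']*')
  | (?P<op><=|>=|<>|<|>|=)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<word>[A-Za-z_][A-Za-z_0-9]*)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"AND", "OR", "NOT", "ABS"}


@dataclass
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise CriterionSyntaxError(
                f"unexpected character {text[pos]!r}", pos
            )
        kind = m.lastgroup
        if kind != "ws":
            tok_text = m.group()
            if kind == "word":
                upper = tok_text.upper()
                if upper in _KEYWORDS:
                    kind, tok_text = upper, upper
                else:
                    raise CriterionSyntaxError(
                        f"unknown function or keyword {tok_text!r} "
                        "(only ABS, AND, OR, NOT are recognized; "
                        "column names must be bracketed)",
                        pos,
                    )
            tokens.append(_Token(kind, tok_text, pos))
        pos = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# parser

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
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
            raise CriterionSyntaxError(
                f"expected {what}, found "
                + (repr(self.cur.text) if self.cur.kind != "eof" else "end of input"),
                self.cur.pos,
            )
        return self.advance()

    def parse(self) -> BoolNode:
        node = self.or_expr()
        if self.cur.kind != "eof":
            raise CriterionSyntaxError(
                f"unexpected trailing input {self.cur.text!r}", self.cur.pos
            )
        return node

    def or_expr(self) -> BoolNode:
        node = self.and_expr()
        while self.cur.kind == "OR":
            self.advance()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> BoolNode:
        node = self.not_expr()
        while self.cur.kind == "AND":
            self.advance()
            node = And(node, self.not_expr())
        return node

    def not_expr(self) -> BoolNode:
        if self.cur.kind == "NOT":
            self.advance()
            return Not(self.not_expr())
        return self.primary()

    def primary(self) -> BoolNode:
        if self.cur.kind == "lparen":
            self.advance()
            node = self.or_expr()
            self.expect("rparen", "')'")
            return node
        return self.comparison()

    def comparison(self) -> Cmp:
        left = self.value()
        if self.cur.kind != "op":
            raise CriterionSyntaxError(
                "expected a comparison operator, found "
                + (repr(self.cur.text) if self.cur.kind != "eof" else "end of input"),
                self.cur.pos,
            )
        op = self.advance().text
        right = self.value()
        return Cmp(op, left, right)

    def value(self) -> ValueNode:
        tok = self.cur
        if tok.kind == "number":
            self.advance()
            return NumberLit(float(tok.text))
        if tok.kind == "string":
            self.advance()
            return StringLit(tok.text[1:-1])
        if tok.kind == "column":
            self.advance()
            name = tok.text[1:-1]
            if not name:
                raise CriterionSyntaxError("empty column name '[]'", tok.pos)
            return ColumnRef(name)
        if tok.kind == "ABS":
            self.advance()
            self.expect("lparen", "'(' after ABS")
            arg = self.value()
            self.expect("rparen", "')'")
            return Abs(arg)
        raise CriterionSyntaxError(
            "expected a value (number, string, [column] or ABS(...)), found "
            + (repr(tok.text) if tok.kind != "eof" else "end of input"),
            tok.pos,
        )


def parse_criterion(text: str) -> Criterion:
    """Parse criterion text into a :class:`Criterion`.

    Raises :class:`CriterionSyntaxError` carrying the character position of
    the failure; unknown function names are reported by name.
    """
    if not text or not text.strip():
        raise CriterionSyntaxError("empty criterion", 0)
    return Criterion(source_text=text, ast=_Parser(text).parse())


# ---------------------------------------------------------------------------
# evaluation (Kleene three-valued logic)

def _describe(node) -> str:
    if isinstance(node, ColumnRef):
        return f"column [{node.name}]"
    if isinstance(node, Abs):
        return _describe(node.arg)
    return "literal"


def _eval_value(node, values: dict):
    if isinstance(node, NumberLit):
        return node.value
    if isinstance(node, StringLit):
        return node.value
    if isinstance(node, ColumnRef):
        return values.get(node.name, MISSING)
    # Abs
    v = _eval_value(node.arg, values)
    if v is MISSING:
        return MISSING
    if isinstance(v, str):
        raise CriterionTypeError(
            f"ABS applied to non-numeric value from {_describe(node.arg)}"
        )
    return abs(v)


def _eval_cmp(node: Cmp, values: dict) -> Optional[bool]:
    left = _eval_value(node.left, values)
    right = _eval_value(node.right, values)
    if left is MISSING or right is MISSING:
        return None
    lstr, rstr = isinstance(left, str), isinstance(right, str)
    if node.op in ("=", "<>"):
        if lstr != rstr:
            raise CriterionTypeError(
                f"cannot compare {_describe(node.left)} with "
                f"{_describe(node.right)}: mixed text and numeric operands"
            )
        return (left == right) if node.op == "=" else (left != right)
    if lstr or rstr:
        offender = node.left if lstr else node.right
        raise CriterionTypeError(
            f"ordering comparison {node.op!r} applied to text value "
            f"from {_describe(offender)} (only = and <> work on text)"
        )
    return {
        "<": left < right,
        "<=": left <= right,
        ">": left > right,
        ">=": left >= right,
    }[node.op]


def _eval_bool(node, values: dict) -> Optional[bool]:
    if isinstance(node, Cmp):
        return _eval_cmp(node, values)
    if isinstance(node, Not):
        v = _eval_bool(node.operand, values)
        return None if v is None else (not v)
    if isinstance(node, And):
        left = _eval_bool(node.left, values)
        right = _eval_bool(node.right, values)
        if left is False or right is False:
            return False
        if left is None or right is None:
            return None
        return True
    # Or
    left = _eval_bool(node.left, values)
    right = _eval_bool(node.right, values)
    if left is True or right is True:
        return True
    if left is None or right is None:
        return None
    return False


def evaluate_criterion(c: Criterion, row) -> Optional[bool]:
    """Evaluate a criterion against one data row.

    ``row`` is anything with a ``values`` mapping (a :class:`~pathora.dataset.
    DataRow`) or a plain dict of column name to value. Returns ``True``,
    ``False`` or ``None`` (undefined: some needed value was missing).
    """
    values = row.values if hasattr(row, "values") and not isinstance(row, dict) else row
    return _eval_bool(c.ast, values)


# ---------------------------------------------------------------------------
# pretty-printing (canonical text that reparses to the same AST)

def _pretty_value(node) -> str:
    if isinstance(node, NumberLit):
        return repr(node.value)
    if isinstance(node, StringLit):
        return f'"{node.value}"'
    if isinstance(node, ColumnRef):
        return f"[{node.name}]"
    return f"ABS({_pretty_value(node.arg)})"


_PREC = {Or: 1, And: 2, Not: 3, Cmp: 4}


def _pretty_bool(node, parent_prec: int = 0) -> str:
    prec = _PREC[type(node)]
    if isinstance(node, Cmp):
        s = f"{_pretty_value(node.left)} {node.op} {_pretty_value(node.right)}"
    elif isinstance(node, Not):
        s = f"NOT {_pretty_bool(node.operand, prec)}"
    elif isinstance(node, And):
        s = f"{_pretty_bool(node.left, prec)} AND {_pretty_bool(node.right, prec + 1)}"
    else:
        s = f"{_pretty_bool(node.left, prec)} OR {_pretty_bool(node.right, prec + 1)}"
    if prec < parent_prec:
        s = f"({s})"
    return s
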