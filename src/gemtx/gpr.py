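"""Gene-protein-reaction (GPR) rule parsing and expression mapping.

A GPR is a Boolean expression over gene ids: ``and`` encodes enzyme complexes
(all subunits required), ``or`` encodes isozymes (any one suffices).  When
mapping transcript abundances onto reactions, each Boolean operator is
replaced by a numeric one — ``and`` by the minimum or the geometric mean of
its operands, ``or`` by the maximum or the sum — giving four mapping schemes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Union

from .errors import GprParseError

__all__ = [
    "GeneLeaf",
    "BoolNode",
    "GprExpression",
    "MappingScheme",
    "parse_gpr",
    "evaluate_gpr",
    "boolean_evaluate",
]


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLeaf:
    gene: str

    def genes(self) -> set[str]:
        return {self.gene}


@dataclass(frozen=True)
class BoolNode:
    op: Literal["and", "or"]
    children: tuple["GprExpression", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise GprParseError(f"{self.op} node needs >=2 operands")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out


GprExpression = Union[GeneLeaf, BoolNode]


@dataclass(frozen=True)
class MappingScheme:
    """Numeric operators substituted for the Boolean GPR operators."""

    and_operator: Literal["MIN", "GEOMETRIC_MEAN"] = "MIN"
    or_operator: Literal["MAX", "SUM"] = "MAX"

    _AND_ALIASES = {"min": "MIN", "gm": "GEOMETRIC_MEAN", "geometric_mean": "GEOMETRIC_MEAN"}
    _OR_ALIASES = {"max": "MAX", "sum": "SUM"}

    @classmethod
    def from_names(cls, and_op: str, or_op: str) -> "MappingScheme":
        try:
            return cls(cls._AND_ALIASES[and_op.lower()], cls._OR_ALIASES[or_op.lower()])
        except KeyError as exc:
            raise ValueError(f"unknown mapping operator {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Parsing: expr := term ('or' term)* ; term := factor ('and' factor)* ;
# factor := '(' expr ')' | gene-id.  'and' binds tighter than 'or'.
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, text: str):
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN.finditer(text)]
        self.pos = 0

    def peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def expr(self) -> GprExpression:
        children = [self.term()]
        while (tok := self.peek()) is not None and tok[0].lower() == "or":
            self.next()
            children.append(self.term())
        if len(children) == 1:
            return children[0]
        flat: list[GprExpression] = []
        for c in children:  # flatten same-operator chains: a or (b or c) == or(a,b,c)
            flat.extend(c.children if isinstance(c, BoolNode) and c.op == "or" else [c])
        return BoolNode("or", tuple(flat))

    def term(self) -> GprExpression:
        children = [self.factor()]
        while (tok := self.peek()) is not None and tok[0].lower() == "and":
            self.next()
            children.append(self.factor())
        if len(children) == 1:
            return children[0]
        flat: list[GprExpression] = []
        for c in children:
            flat.extend(c.children if isinstance(c, BoolNode) and c.op == "and" else [c])
        return BoolNode("and", tuple(flat))

    def factor(self) -> GprExpression:
        tok, at = self.next()
        if tok == "(":
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parentheses", at)
            self.next()
            return inner
        if tok == ")":
            raise GprParseError("unexpected ')'", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", at)
        return GeneLeaf(tok)


def parse_gpr(text: str | None) -> Optional[GprExpression]:
    """Parse a GPR string into an AST; empty/whitespace text parses to ``None``.

    Keywords ``and``/``or`` are case-insensitive, ``and`` binds tighter than
    ``or``, and parentheses group arbitrarily deep.
    """
    if text is None or not text.strip():
        return None
    parser = _Parser(text)
    tree = parser.expr()
    if (extra := parser.peek()) is not None:
        raise GprParseError(f"unexpected token {extra[0]!r}", extra[1])
    return tree


# ---------------------------------------------------------------------------
# Numeric evaluation
# ---------------------------------------------------------------------------

def _geometric_mean(values: list[float]) -> float:
    # limit of the formula at 0: any zero operand gives 0, no epsilon injected
    if any(v == 0 for v in values):
        return 0.0
    return math.exp(sum(math.log(v) for v in values) / len(values))


def evaluate_gpr(
    expr: Optional[GprExpression],
    expression: Mapping[str, float],
    scheme: MappingScheme = MappingScheme(),
    missing_policy: Literal["skip", "undefined"] = "skip",
) -> Optional[float]:
    """Map gene-expression values onto a GPR tree; ``None`` means undefined.

    Leaves return their measured value.  ``and`` nodes combine children with
    MIN or the geometric mean, ``or`` nodes with MAX or SUM.  Under
    ``missing_policy='skip'`` an unmeasured operand is dropped (a node whose
    operands are all undefined is itself undefined); under ``'undefined'`` one
    missing gene makes the whole expression undefined.
    """
    if expr is None:
        return None
    if isinstance(expr, GeneLeaf):
        value = expression.get(expr.gene)
        if value is None:
            return None
        if value < 0:
            raise ValueError(f"negative expression value for {expr.gene!r}")
        return float(value)
    # Operators are n-ary over the flattened operand list: a chain like
    # "a and (b and c)" means one and-node over (a, b, c).  This is what makes
    # the geometric mean (not associative pairwise) well defined on chains.
    operands: list[GprExpression] = []
    stack = list(expr.children)
    while stack:
        child = stack.pop(0)
        if isinstance(child, BoolNode) and child.op == expr.op:
            stack[0:0] = list(child.children)
        else:
            operands.append(child)
    parts: list[float] = []
    for child in operands:
        sub = evaluate_gpr(child, expression, scheme, missing_policy)
        if sub is None:
            if missing_policy == "undefined":
                return None
            continue
        parts.append(sub)
    if not parts:
        return None
    if expr.op == "and":
        return min(parts) if scheme.and_operator == "MIN" else _geometric_mean(parts)
    return max(parts) if scheme.or_operator == "MAX" else float(sum(parts))


def boolean_evaluate(expr: Optional[GprExpression], deleted_genes: set[str]) -> bool:
    """Can the reaction still be catalyzed after knocking out ``deleted_genes``?

    A leaf is satisfied iff its gene is not deleted; ``and`` requires all
    children, ``or`` any.  An empty GPR (``None``) never blocks a reaction.
    """
    if expr is None:
        return True
    if isinstance(expr, GeneLeaf):
        return expr.gene not in deleted_genes
    results = (boolean_evaluate(c, deleted_genes) for c in expr.children)
    return all(results) if expr.op == "and" else any(results)
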