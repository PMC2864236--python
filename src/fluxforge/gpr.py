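"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean formula over gene identifiers built from AND, OR and
parentheses (no negation): AND encodes subunits of a complex that are all
required, OR encodes isozymes where any one suffices.  Evaluation is plain
boolean -- isozyme dosage is ignored, since deletions are on/off events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


class GeneRuleError(ValueError):
    """Raised when a GPR expression cannot be parsed."""


@dataclass(frozen=True)
class _Node:
    op: str  # "gene", "and", "or"
    gene: str | None = None
    children: tuple = ()

    def evaluate(self, active: Mapping[str, bool]) -> bool:
        if self.op == "gene":
            return active.get(self.gene, True)
        vals = (c.evaluate(active) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def genes(self) -> frozenset:
        if self.op == "gene":
            return frozenset({self.gene})
        out: frozenset = frozenset()
        for c in self.children:
            out |= c.genes()
        return out


class GeneRule:
    """A parsed boolean gene-association formula.

    >>> r = GeneRule("(g1 and g2) or g3")
    >>> r.evaluate({"g1": False})
    True
    >>> r.evaluate({"g1": False, "g3": False})
    False
    """

    def __init__(self, expression: str):
        expression = expression.strip()
        if not expression:
            raise GeneRuleError("empty gene rule")
        self.expression = expression
        self._root = _parse(expression)
        self.genes = self._root.genes()

    def evaluate(self, active: Mapping[str, bool]) -> bool:
        """Truth value with the given gene states; absent genes are True."""
        return self._root.evaluate(active)

    def __eq__(self, other):
        return isinstance(other, GeneRule) and self._root == other._root

    def __hash__(self):
        return hash(self._root)

    def __repr__(self):
        return f"GeneRule({self.expression!r})"


def _parse(expr: str) -> _Node:
    tokens = _TOKEN.findall(expr)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> _Node:
        left = parse_and()
        children = [left]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else _Node("or", children=tuple(children))

    def parse_and() -> _Node:
        left = parse_atom()
        children = [left]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else _Node("and", children=tuple(children))

    def parse_atom() -> _Node:
        tok = peek()
        if tok is None:
            raise GeneRuleError(f"unexpected end of rule: {expr!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GeneRuleError(f"unbalanced parentheses in {expr!r}")
            take()
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GeneRuleError(f"unexpected token {tok!r} in {expr!r}")
        return _Node("gene", gene=take())

    root = parse_or()
    if pos != len(tokens):
        raise GeneRuleError(f"trailing tokens in {expr!r}")
    return root


def rule_or_none(expression: str | None) -> GeneRule | None:
    if expression is None or not expression.strip():
        return None
    return GeneRule(expression)
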