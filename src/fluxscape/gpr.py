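"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene products must be expressed for a reaction's
enzyme to be available, as a boolean expression over gene identifiers with
``and`` / ``or`` connectives, e.g. ``(g1 and g2) or g3`` for an isozyme of
a two-subunit complex.  ``and`` binds tighter than ``or``; parentheses
override precedence; keywords are case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import ParseError

__all__ = ["GPRNode", "parse_gpr", "evaluate_gpr", "gpr_to_string"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GPRNode:
    """Node of a GPR expression tree.

    ``kind`` is ``"GENE"`` (leaf, carries ``gene_id``), ``"AND"`` or
    ``"OR"`` (internal, carries ``children``).
    """

    kind: str
    gene_id: str | None = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene_id or self.children:
                raise ValueError("GENE node needs a gene_id and no children")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 1 or self.gene_id is not None:
                raise ValueError(f"{self.kind} node needs >=1 children and no gene_id")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> frozenset[str]:
        """Set of gene ids referenced anywhere under this node."""
        if self.kind == "GENE":
            return frozenset((self.gene_id,))
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _Parser:
    """Recursive-descent parser: expr := term ('or' term)*; term := factor ('and' factor)*."""

    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError(f"unexpected end of GPR rule {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self) -> GPRNode:
        node = self.expr()
        if self.peek() is not None:
            raise ParseError(f"trailing tokens after position {self.pos} in GPR rule {self.rule!r}")
        return node

    def expr(self) -> GPRNode:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        return GPRNode("OR", children=tuple(terms))

    def term(self) -> GPRNode:
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            factors.append(self.factor())
        if len(factors) == 1:
            return factors[0]
        return GPRNode("AND", children=tuple(factors))

    def factor(self) -> GPRNode:
        tok = self.peek()
        if tok is None:
            raise ParseError(f"empty operand in GPR rule {self.rule!r}")
        if tok == "(":
            self.take()
            node = self.expr()
            if self.peek() != ")":
                raise ParseError(f"unbalanced parentheses in GPR rule {self.rule!r}")
            self.take()
            return node
        if tok == ")":
            raise ParseError(f"unbalanced parentheses in GPR rule {self.rule!r}")
        if tok.lower() in ("and", "or"):
            raise ParseError(f"operator {tok!r} where operand expected in GPR rule {self.rule!r}")
        self.take()
        return GPRNode("GENE", gene_id=tok)


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR rule string into an expression tree.

    ``and`` binds tighter than ``or``; keywords are case-insensitive; gene
    ids are any whitespace/parenthesis-free tokens.

    Raises
    ------
    ParseError
        On unbalanced parentheses, empty operands, or an empty rule.
    """
    tokens = _tokenize(rule)
    if not tokens:
        raise ParseError("empty GPR rule")
    return _Parser(tokens, rule).parse()


def gpr_to_string(node: GPRNode) -> str:
    """Serialize a GPR tree to a normalized rule string (round-trip safe)."""
    if node.kind == "GENE":
        return node.gene_id  # type: ignore[return-value]
    sep = " and " if node.kind == "AND" else " or "
    parts = []
    for child in node.children:
        text = gpr_to_string(child)
        if child.kind in ("AND", "OR"):
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


def evaluate_gpr(
    node: GPRNode,
    present: Mapping[str, bool],
    default_present: bool = True,
) -> bool:
    """Evaluate a GPR tree under a (possibly partial) gene presence map.

    Genes missing from ``present`` take ``default_present``; by default a
    transcript that was never measured leaves the reaction unconstrained
    (treated as expressed).
    """
    if node.kind == "GENE":
        return bool(present.get(node.gene_id, default_present))
    if node.kind == "AND":
        return all(evaluate_gpr(c, present, default_present) for c in node.children)
    return any(evaluate_gpr(c, present, default_present) for c in node.children)
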