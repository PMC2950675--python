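"""Gene-protein-reaction (GPR) boolean rules.

A GPR links a reaction to the genes whose products catalyze it: ``and``
joins subunits of a complex (all required), ``or`` joins isozymes (any
suffices). Rules are small boolean expressions over gene identifiers,
e.g. ``(g1 and g2) or g3``.

Two evaluation modes are supported:

* knockout — a deletion semantics where each leaf is true iff its gene
  has not been deleted; the rule value says whether the reaction can
  still be catalyzed.
* expression — a quantitative semantics where each leaf takes its
  gene's expression value, ``and`` takes the minimum over children and
  ``or`` the maximum; genes without data are excluded from the
  aggregation, and a rule with no data at all evaluates to ``None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

__all__ = [
    "GPRTree",
    "GPRParseError",
    "EMPTY_GPR",
    "parse_gpr",
    "evaluate_gpr_knockout",
    "evaluate_gpr_expression",
    "limiting_genes",
]

GENE = "gene"
AND = "and"
OR = "or"
EMPTY = "empty"

_KEYWORDS = {"and", "or"}


class GPRParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the offending position."""


@dataclass(frozen=True)
class GPRTree:
    """Immutable GPR expression tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``, ``"empty"``.
    Leaves carry a non-empty ``gene``; ``and``/``or`` nodes carry at
    least two ``children``.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple["GPRTree", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == GENE:
            if not self.gene:
                raise ValueError("gene leaf requires a non-empty gene id")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >=2 children")
        elif self.kind != EMPTY:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    @property
    def is_empty(self) -> bool:
        return self.kind == EMPTY

    def genes(self) -> set[str]:
        """All gene ids appearing in the rule."""
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.kind == GENE:
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child._iter_genes()

    def to_string(self) -> str:
        """Canonical rendering: operators lowercase, non-leaf children parenthesized."""
        if self.kind == EMPTY:
            return ""
        if self.kind == GENE:
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.kind in (AND, OR):
                s = f"({s})"
            parts.append(s)
        return f" {self.kind} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GPRTree(EMPTY)


def gene_leaf(gene: str) -> GPRTree:
    return GPRTree(GENE, gene=gene)


def and_node(*children: GPRTree) -> GPRTree:
    return GPRTree(AND, children=tuple(children))


def or_node(*children: GPRTree) -> GPRTree:
    return GPRTree(OR, children=tuple(children))


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    # recursive descent; grammar: expr := term ("or" term)*, term := factor ("and" factor)*,
    # factor := "(" expr ")" | gene-token. `and` binds tighter than `or`.

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(
                f"unexpected end of rule at position {len(self.text)}: {self.text!r}"
            )
        self.pos += 1
        return tok

    def parse(self) -> GPRTree:
        tree = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(
                f"unexpected token {tok[0]!r} at position {tok[1]} in {self.text!r}"
            )
        return tree

    def expr(self) -> GPRTree:
        children = [self.term()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "or":
                break
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else _flatten(OR, children)

    def term(self) -> GPRTree:
        children = [self.factor()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "and":
                break
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten(AND, children)

    def factor(self) -> GPRTree:
        tok = self.next()
        text, pos = tok
        if text == "(":
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError(
                    f"unbalanced parenthesis opened at position {pos} in {self.text!r}"
                )
            self.next()
            return inner
        if text == ")" or text.lower() in _KEYWORDS:
            raise GPRParseError(
                f"unexpected token {text!r} at position {pos} in {self.text!r}"
            )
        return gene_leaf(text)


def _flatten(kind: str, children: list[GPRTree]) -> GPRTree:
    flat: list[GPRTree] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GPRTree(kind, children=tuple(flat))


def parse_gpr(text: str) -> GPRTree:
    """Parse a boolean GPR rule string into a :class:`GPRTree`.

    Operators ``and``/``or`` are case-insensitive and whitespace is
    ignored; gene ids are arbitrary non-keyword, non-parenthesis
    tokens. An empty (or whitespace-only) string gives the EMPTY tree
    (no gene association).
    """
    if not text or not text.strip():
        return EMPTY_GPR
    return _Parser(text).parse()


def evaluate_gpr_knockout(tree: GPRTree, deleted_genes: set[str]) -> bool:
    """True iff the reaction survives deleting ``deleted_genes``.

    EMPTY rules (spontaneous / orphan reactions) always survive.
    """
    if tree.kind == EMPTY:
        return True
    if tree.kind == GENE:
        return tree.gene not in deleted_genes
    results = (evaluate_gpr_knockout(c, deleted_genes) for c in tree.children)
    return all(results) if tree.kind == AND else any(results)


def evaluate_gpr_expression(
    tree: GPRTree, gene_values: Mapping[str, float]
) -> Optional[float]:
    """Reaction-level expression score: min over ``and``, max over ``or``.

    Genes missing from ``gene_values`` carry no data and are skipped;
    if no leaf has data (or the tree is EMPTY) the result is ``None``,
    which downstream consumers treat as "no evidence, unpenalized".
    """
    if tree.kind == EMPTY:
        return None
    if tree.kind == GENE:
        return gene_values.get(tree.gene)  # type: ignore[arg-type]
    vals = [
        v
        for v in (evaluate_gpr_expression(c, gene_values) for c in tree.children)
        if v is not None
    ]
    if not vals:
        return None
    return min(vals) if tree.kind == AND else max(vals)


def limiting_genes(tree: GPRTree, gene_values: Mapping[str, float]) -> set[str]:
    """Genes whose expression value determines the rule's evaluated score.

    A gene is limiting when its value equals the tree's evaluated value
    and it lies on a min/max-selecting path from the root; ties return
    every tied gene. Requires the tree to evaluate to a value.
    """
    value = evaluate_gpr_expression(tree, gene_values)
    if value is None:
        raise ValueError("limiting_genes requires a tree that evaluates to a value")
    return _limiting(tree, gene_values)


def _limiting(tree: GPRTree, gene_values: Mapping[str, float]) -> set[str]:
    if tree.kind == GENE:
        return {tree.gene} if tree.gene in gene_values else set()  # type: ignore[arg-type]
    value = evaluate_gpr_expression(tree, gene_values)
    out: set[str] = set()
    for child in tree.children:
        cv = evaluate_gpr_expression(child, gene_values)
        if cv is not None and cv == value:
            out |= _limiting(child, gene_values)
    return out
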