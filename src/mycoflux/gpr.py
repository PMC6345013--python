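"""Gene-protein-reaction (GPR) boolean rules.

A GPR states which gene combinations provide the enzyme(s) for a reaction,
e.g. ``"PFK1 and PFK2"`` for a hetero-octameric complex or ``"HXK1 or GLK1"``
for isozymes.  ``and`` binds tighter than ``or``; parentheses override.
An empty rule means the reaction needs no gene evidence and is always active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence, Union


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


Node = Union[Gene, And, Or]


class GPRExpression:
    """Immutable boolean expression tree over gene identifiers.

    ``root is None`` encodes the empty rule (always satisfiable).
    """

    __slots__ = ("root",)

    def __init__(self, root: Optional[Node] = None):
        object.__setattr__(self, "root", root)

    # -- construction -----------------------------------------------------
    @classmethod
    def empty(cls) -> "GPRExpression":
        return cls(None)

    @classmethod
    def single(cls, gene: str) -> "GPRExpression":
        return cls(Gene(gene))

    # -- queries ----------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset:
        """Set of gene ids appearing anywhere in the expression."""
        out = set()

        def walk(node: Node) -> None:
            if isinstance(node, Gene):
                out.add(node.name)
            else:
                for child in node.children:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, knocked_out: Sequence[str] = ()) -> bool:
        """True iff the rule is satisfied with ``knocked_out`` genes absent.

        Genes not listed are assumed present; the empty rule is always true.
        """
        ko = frozenset(knocked_out)

        def walk(node: Node) -> bool:
            if isinstance(node, Gene):
                return node.name not in ko
            if isinstance(node, And):
                return all(walk(c) for c in node.children)
            return any(walk(c) for c in node.children)

        return True if self.root is None else walk(self.root)

    def substitute(self, mapping: Mapping[str, Sequence[str]]) -> "GPRExpression":
        """Rewrite each gene leaf using ``mapping`` (old id -> new id set).

        Leaves mapping to several ids become an OR over them; leaves absent
        from the mapping become unsatisfiable and are simplified away.  If
        the whole expression becomes unsatisfiable the result is an
        expression whose :meth:`evaluate` is always False, represented as
        ``None`` sentinel — callers should check :meth:`substitute` via the
        returned ``(expr, satisfiable)`` pair.
        """
        FALSE = object()

        def walk(node: Node):
            if isinstance(node, Gene):
                targets = sorted(set(mapping.get(node.name, ())))
                if not targets:
                    return FALSE
                if len(targets) == 1:
                    return Gene(targets[0])
                return Or(tuple(Gene(t) for t in targets))
            parts = [walk(c) for c in node.children]
            if isinstance(node, And):
                if any(p is FALSE for p in parts):
                    return FALSE
                return And(tuple(parts)) if len(parts) > 1 else parts[0]
            parts = [p for p in parts if p is not FALSE]
            if not parts:
                return FALSE
            return Or(tuple(parts)) if len(parts) > 1 else parts[0]

        if self.root is None:
            return GPRExpression.empty()
        new_root = walk(self.root)
        if new_root is FALSE:
            raise UnsatisfiableGPR("no mapped gene satisfies the rule")
        return GPRExpression(new_root)

    # -- serialization ----------------------------------------------------
    def to_string(self) -> str:
        """Canonical string; reparsing yields an equivalent tree."""

        def walk(node: Node, parent_and: bool) -> str:
            if isinstance(node, Gene):
                return node.name
            if isinstance(node, And):
                return " and ".join(walk(c, True) for c in node.children)
            inner = " or ".join(walk(c, False) for c in node.children)
            return f"({inner})" if parent_and else inner

        return "" if self.root is None else walk(self.root, False)

    def __str__(self) -> str:
        return self.to_string()

    def __repr__(self) -> str:
        return f"GPRExpression({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GPRExpression) and self.root == other.root

    def __hash__(self) -> int:
        return hash(self.root)


class UnsatisfiableGPR(ValueError):
    """Raised when a substitution leaves no way to satisfy the rule."""


# -- parsing ---------------------------------------------------------------

_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[tuple]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield (ch, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            yield (low, i)
        else:
            yield ("gene", i, word)
        i = j
    yield ("end", n)


def parse_gpr(text: str) -> GPRExpression:
    """Parse a GPR string into an expression tree.

    Grammar (``and`` binds tighter than ``or``, keywords case-insensitive)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := GENE | "(" expr ")"
    """
    tokens = list(_tokenize(text))
    if tokens[0][0] == "end":
        return GPRExpression.empty()
    pos = 0

    def peek():
        return tokens[pos]

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_factor() -> Node:
        tok = peek()
        if tok[0] == "gene":
            advance()
            return Gene(tok[2])
        if tok[0] == "(":
            advance()
            node = parse_expr()
            closing = peek()
            if closing[0] != ")":
                raise GPRParseError("unbalanced parentheses: expected ')'", closing[1])
            advance()
            return node
        raise GPRParseError("empty operand: expected a gene id or '('", tok[1])

    def parse_term() -> Node:
        parts = [parse_factor()]
        while peek()[0] == "and":
            advance()
            parts.append(parse_factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_expr() -> Node:
        parts = [parse_term()]
        while peek()[0] == "or":
            advance()
            parts.append(parse_term())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    root = parse_expr()
    trailing = peek()
    if trailing[0] != "end":
        raise GPRParseError(f"unexpected token {trailing[0]!r}", trailing[1])
    return GPRExpression(root)
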