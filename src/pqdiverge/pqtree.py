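"""PQ-tree data model for gene-cluster structures.

A PQ-tree is a rooted ordered tree over signed gene leaves.  The children
of a P-node may be permuted arbitrarily, the children of a Q-node may only
be kept in order or reversed as a block; leaves carry a gene identifier and
a strand sign.  The frontier (left-to-right leaf sequence) of the tree, as
given, is the reference gene order of the cluster.

Every node carries a *color*: a unique integer, assigned in preorder at
parse time, that survives any reordering of the tree.  Equivalence between
a tree and a reordered copy of it is tracked by color only, never by
structural matching.

Index conventions: signed strings use 1-based positions and inclusive
slices throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "SignedString",
    "PQNode",
    "PQTree",
    "TreeFormatError",
    "parse_tree",
    "parse_signed_string",
    "frontier",
    "node_sign",
    "is_flipped",
    "flip_correction",
    "P",
    "Q",
    "LEAF",
]

P = "P"
Q = "Q"
LEAF = "LEAF"

PLUS = 1
MINUS = -1


class TreeFormatError(ValueError):
    """Raised for malformed tree or signed-string text."""


def _sign_str(sign: int) -> str:
    return "+" if sign > 0 else "-"


class SignedString:
    """An immutable sequence of (gene-id, sign) tokens.

    Positions are 1-based and slices inclusive: ``s[i]`` is the i-th token,
    ``s.slice(i, j)`` is tokens i..j.
    """

    __slots__ = ("tokens",)

    def __init__(self, tokens: Iterable[tuple[str, int]]):
        toks = []
        for label, sign in tokens:
            if sign not in (PLUS, MINUS):
                raise ValueError(f"sign must be +1 or -1, got {sign!r}")
            toks.append((str(label), sign))
        self.tokens: tuple[tuple[str, int], ...] = tuple(toks)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.tokens)

    def __getitem__(self, pos: int) -> tuple[str, int]:
        """1-based access: ``s[1]`` is the first token."""
        if not 1 <= pos <= len(self.tokens):
            raise IndexError(f"position {pos} out of range 1..{len(self.tokens)}")
        return self.tokens[pos - 1]

    def slice(self, i: int, j: int) -> "SignedString":
        """Inclusive 1-based slice S[i:j] = s_i ... s_j."""
        if i > j:
            return SignedString(())
        if not (1 <= i and j <= len(self.tokens)):
            raise IndexError(f"slice {i}:{j} out of range 1..{len(self.tokens)}")
        return SignedString(self.tokens[i - 1 : j])

    def label(self, pos: int) -> str:
        return self[pos][0]

    def sign(self, pos: int) -> int:
        return self[pos][1]

    def labels(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    def reverse_and_negate(self) -> "SignedString":
        """The same gene order read from the opposite strand."""
        return SignedString((lab, -sg) for lab, sg in reversed(self.tokens))

    def __eq__(self, other) -> bool:
        return isinstance(other, SignedString) and self.tokens == other.tokens

    def __hash__(self) -> int:
        return hash(self.tokens)

    def __str__(self) -> str:
        return " ".join(f"{_sign_str(sg)}{lab}" for lab, sg in self.tokens)

    def __repr__(self) -> str:
        return f"SignedString({str(self)!r})"


def parse_signed_string(text: str) -> SignedString:
    """Parse whitespace-separated signed tokens, e.g. ``+cog0001 -cog0042``.

    A token without an explicit sign is positive.
    """
    tokens = []
    for raw in text.split():
        if raw.startswith("+"):
            lab, sg = raw[1:], PLUS
        elif raw.startswith("-"):
            lab, sg = raw[1:], MINUS
        else:
            lab, sg = raw, PLUS
        if not lab:
            raise TreeFormatError(f"empty gene identifier in token {raw!r}")
        tokens.append((lab, sg))
    return SignedString(tokens)


@dataclass(eq=False)
class PQNode:
    """A node of a PQ-tree.

    ``kind`` is ``P``, ``Q`` or ``LEAF``.  Leaves carry ``label`` and
    ``leaf_sign``; internal nodes carry an ordered ``children`` list.
    ``color`` uniquely identifies the node within its tree and is preserved
    by any reordering.
    """

    kind: str
    children: list["PQNode"] = field(default_factory=list)
    label: Optional[str] = None
    leaf_sign: int = PLUS
    color: int = -1

    def is_leaf(self) -> bool:
        return self.kind == LEAF

    def iter_preorder(self) -> Iterator["PQNode"]:
        yield self
        for c in self.children:
            yield from c.iter_preorder()

    def iter_postorder(self) -> Iterator["PQNode"]:
        for c in self.children:
            yield from c.iter_postorder()
        yield self

    def leaves(self) -> list["PQNode"]:
        return [v for v in self.iter_preorder() if v.is_leaf()]

    @property
    def span(self) -> int:
        return 1 if self.is_leaf() else sum(c.span for c in self.children)

    def copy(self) -> "PQNode":
        return PQNode(
            kind=self.kind,
            children=[c.copy() for c in self.children],
            label=self.label,
            leaf_sign=self.leaf_sign,
            color=self.color,
        )

    def validate(self) -> None:
        if self.is_leaf():
            if self.children:
                raise TreeFormatError("leaf with children")
            if not self.label:
                raise TreeFormatError("leaf without a label")
        else:
            if self.kind not in (P, Q):
                raise TreeFormatError(f"unknown node kind {self.kind!r}")
            if len(self.children) < 2:
                raise TreeFormatError(
                    f"internal {self.kind}-node needs at least 2 children, "
                    f"got {len(self.children)}"
                )
            for c in self.children:
                c.validate()

    def __repr__(self) -> str:
        if self.is_leaf():
            return f"<leaf {_sign_str(self.leaf_sign)}{self.label} #{self.color}>"
        return f"<{self.kind}-node #{self.color} x{len(self.children)}>"


class PQTree:
    """A colored PQ-tree with derived statistics.

    ``m`` (= ``n`` for permutation inputs) is the leaf count, ``m_p`` /
    ``m_q`` count P- and Q-nodes, ``gamma`` is the maximum out-degree.
    """

    def __init__(self, root: PQNode, assign_colors: bool = True):
        root.validate()
        self.root = root
        if assign_colors:
            for color, node in enumerate(root.iter_preorder()):
                node.color = color
        colors = [v.color for v in root.iter_preorder()]
        if len(set(colors)) != len(colors):
            raise TreeFormatError("node colors are not unique")
        self._by_color = {v.color: v for v in root.iter_preorder()}

    @property
    def m(self) -> int:
        return self.root.span

    n = m  # for permutation instances the string length equals the leaf count

    @property
    def m_p(self) -> int:
        return sum(1 for v in self.root.iter_preorder() if v.kind == P)

    @property
    def m_q(self) -> int:
        return sum(1 for v in self.root.iter_preorder() if v.kind == Q)

    @property
    def gamma(self) -> int:
        degrees = [len(v.children) for v in self.root.iter_preorder() if not v.is_leaf()]
        return max(degrees, default=0)

    def node(self, color: int) -> PQNode:
        return self._by_color[color]

    def leaves(self) -> list[PQNode]:
        return self.root.leaves()

    def __repr__(self) -> str:
        return (
            f"PQTree(m={self.m}, m_p={self.m_p}, m_q={self.m_q}, "
            f"gamma={self.gamma})"
        )


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[str]:
    out: list[str] = []
    cur = ""
    for ch in text:
        if ch in "()":
            if cur:
                out.append(cur)
                cur = ""
            out.append(ch)
        elif ch.isspace():
            if cur:
                out.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out


def _parse_node(tokens: list[str], idx: int) -> tuple[PQNode, int]:
    tok = tokens[idx]
    if tok == "(":
        if idx + 1 >= len(tokens) or tokens[idx + 1] not in (P, Q, "p", "q"):
            raise TreeFormatError("expected node kind 'P' or 'Q' after '('")
        kind = tokens[idx + 1].upper()
        idx += 2
        children: list[PQNode] = []
        while idx < len(tokens) and tokens[idx] != ")":
            child, idx = _parse_node(tokens, idx)
            children.append(child)
        if idx >= len(tokens):
            raise TreeFormatError("unbalanced parenthesis: missing ')'")
        return PQNode(kind=kind, children=children), idx + 1
    if tok == ")":
        raise TreeFormatError("unexpected ')'")
    # signed leaf token; sign defaults to '+'
    if tok.startswith("+"):
        lab, sg = tok[1:], PLUS
    elif tok.startswith("-"):
        lab, sg = tok[1:], MINUS
    else:
        lab, sg = tok, PLUS
    if not lab:
        raise TreeFormatError(f"empty leaf label in token {tok!r}")
    return PQNode(kind=LEAF, label=lab, leaf_sign=sg), idx + 1


def parse_tree(text: str) -> PQTree:
    """Parse the parenthesized tree format.

    Grammar: ``node := signed-leaf | "(" ("P"|"Q") node node+ ")"``.
    Colors are assigned in preorder.  Examples::

        (P +a +b)
        (P (P +a (Q +b +c) +d) +e +f)
    """
    tokens = _tokenize(text)
    if not tokens:
        raise TreeFormatError("empty tree text")
    root, idx = _parse_node(tokens, 0)
    if idx != len(tokens):
        raise TreeFormatError(f"trailing input after tree: {tokens[idx:]!r}")
    return PQTree(root)


def serialize_tree(tree: Union[PQTree, PQNode]) -> str:
    """Inverse of :func:`parse_tree` (round-trips structure and signs)."""
    node = tree.root if isinstance(tree, PQTree) else tree

    def rec(v: PQNode) -> str:
        if v.is_leaf():
            return f"{_sign_str(v.leaf_sign)}{v.label}"
        return "(" + v.kind + " " + " ".join(rec(c) for c in v.children) + ")"

    return rec(node)


def tree_to_json(tree: Union[PQTree, PQNode]) -> dict:
    node = tree.root if isinstance(tree, PQTree) else tree
    if node.is_leaf():
        return {"kind": "LEAF", "label": node.label,
                "sign": _sign_str(node.leaf_sign)}
    return {"kind": node.kind,
            "children": [tree_to_json(c) for c in node.children]}


def tree_from_json(obj: dict) -> PQTree:
    def rec(o: dict) -> PQNode:
        kind = o.get("kind")
        if kind == "LEAF":
            sg = MINUS if o.get("sign") == "-" else PLUS
            return PQNode(kind=LEAF, label=o["label"], leaf_sign=sg)
        return PQNode(kind=kind, children=[rec(c) for c in o.get("children", [])])

    return PQTree(rec(obj))


# ---------------------------------------------------------------------------
# Frontier, signs, flips
# ---------------------------------------------------------------------------

def convert_two_child_q_to_p(tree: PQTree) -> PQTree:
    """Optional preprocessing: turn 2-child Q-nodes of height > 1 into P-nodes.

    In such nodes both child orders are typically observed, which matches
    the semantics of a P-node better; off by default because it changes
    the model, not the algorithm.
    """
    root = tree.root.copy()

    def rec(v: PQNode) -> None:
        if v.is_leaf():
            return
        if (
            v.kind == Q
            and len(v.children) == 2
            and any(not c.is_leaf() for c in v.children)
        ):
            v.kind = P
        for c in v.children:
            rec(c)

    rec(root)
    return PQTree(root, assign_colors=False)


def frontier(tree: Union[PQTree, PQNode]) -> SignedString:
    """F(T): the signed leaf sequence read left to right."""
    node = tree.root if isinstance(tree, PQTree) else tree
    return SignedString((v.label, v.leaf_sign) for v in node.leaves())


def node_sign(x: PQNode) -> frozenset[int]:
    """The majority sign of the leaves below ``x``.

    Returns ``{+1}``, ``{-1}``, or ``{+1, -1}`` when positive and negative
    leaves are equally many (the tie is allowed to act as either sign).
    """
    if x.is_leaf():
        return frozenset((x.leaf_sign,))
    pos = sum(1 for v in x.leaves() if v.leaf_sign == PLUS)
    neg = x.span - pos
    if pos > neg:
        return frozenset((PLUS,))
    if neg > pos:
        return frozenset((MINUS,))
    return frozenset((PLUS, MINUS))


def sign_from_pos(pos: int, size: int) -> frozenset[int]:
    """Majority sign of a unit with ``pos`` positive leaves out of ``size``."""
    if 2 * pos > size:
        return frozenset((PLUS,))
    if 2 * pos < size:
        return frozenset((MINUS,))
    return frozenset((PLUS, MINUS))


def pos_consistent(pos: int, sign: int, size: int, k_t: int = 0) -> bool:
    """Whether a positive-leaf count is consistent with a unit sign.

    ``sign=+`` requires ``pos >= (size - k_t)/2``; ``sign=-`` requires
    ``pos <= (size - k_t)/2`` (non-strict on both sides, so an exact tie is
    consistent with either sign).
    """
    half = Fraction(size - k_t, 2)
    return pos >= half if sign == PLUS else pos <= half


def _surviving_children(x: PQNode, present: set[int]) -> list[PQNode]:
    return [c for c in x.children if any(v.color in present for v in c.leaves())]


def is_flipped(x: PQNode, x_ordered: PQNode) -> int:
    """1 if ``x_ordered`` is a flipped copy of ``x``, else 0.

    For leaves: the sign is reversed.  For internal nodes: every child that
    was not deleted is itself flipped, and the surviving children appear in
    reversed order.  ``x_ordered`` must share ``x``'s color (it is a
    reordered, possibly leaf-deleted copy).
    """
    if x.color != x_ordered.color:
        raise ValueError(
            f"color mismatch: {x.color} vs {x_ordered.color} "
            "(is_flipped compares a node with its reordered copy)"
        )
    if x.is_leaf():
        if not x_ordered.is_leaf():
            raise ValueError("leaf compared with internal node of same color")
        return 1 if x.leaf_sign == -x_ordered.leaf_sign else 0
    present = {v.color for v in x_ordered.leaves()}
    surv = _surviving_children(x, present)
    ordered_by_color = {c.color: c for c in x_ordered.children}
    # surviving children must appear in exactly reversed order
    surv_colors = [c.color for c in surv]
    ordered_colors = [c.color for c in x_ordered.children]
    if ordered_colors != list(reversed(surv_colors)):
        return 0
    for c in surv:
        if not is_flipped(c, ordered_by_color[c.color]):
            return 0
    return 1


def flip_correction(x: PQNode, x_ordered: PQNode, delta_q_flip) -> Fraction:
    """Refund of child flip penalties when a whole node flips as one event.

    Returns 0 unless every non-deleted child of ``x`` is flipped; otherwise
    returns ``delta_q_flip`` times the number of non-deleted children that
    are leaves or Q-nodes (P-node children carry no flip penalty of their
    own, so nothing is refunded for them).
    """
    if x.is_leaf():
        return Fraction(0)
    present = {v.color for v in x_ordered.leaves()}
    surv = _surviving_children(x, present)
    ordered_by_color = {}
    for c in x_ordered.children:
        ordered_by_color[c.color] = c
    refundable = 0
    for c in surv:
        co = ordered_by_color.get(c.color)
        if co is None:
            return Fraction(0)
        if not is_flipped(c, co):
            return Fraction(0)
        if c.is_leaf() or c.kind == Q:
            refundable += 1
    return Fraction(delta_q_flip) * refundable
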