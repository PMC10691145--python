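"""Jump violations for P-node reorderings.

Reordering the children of a P-node is modeled as block moves.  A moved
unit of span t costs (t-1)/2, so single leaves move for free and large
blocks are increasingly expensive.  The minimal total cost is the minimum
weight vertex cover of the *jump graph*: vertices are the P-node's
(surviving) children weighted by (span-1)/2, and an edge joins every pair
of children that changed their signed order between the original and the
derived arrangement — at least one endpoint of each such pair must have
moved.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Hashable, Sequence

import networkx as nx

from .breakpoints import signs_compatible
from .pqtree import PQNode, node_sign

__all__ = [
    "pair_changed_signed_order",
    "changed_signed_order",
    "build_jump_graph",
    "jump_graph_from_entries",
    "min_weight_vertex_cover",
    "jump_violation",
    "jump_weight",
]


def jump_weight(span: int) -> Fraction:
    """Weight of a unit of the given span: (span - 1) / 2."""
    return Fraction(span - 1, 2)


def pair_changed_signed_order(
    order_preserved: bool,
    a_orig_sign,
    a_deriv_sign,
    b_orig_sign,
    b_deriv_sign,
) -> bool:
    """Change-of-signed-order test for one pair of children.

    The pair did *not* change its signed order iff the derived relative
    order is preserved with both signs kept, or reversed with both signs
    negated.  Signs may be scalars or tie sets (a tie satisfies either
    requirement).
    """
    if order_preserved:
        kept = signs_compatible(a_orig_sign, a_deriv_sign) and signs_compatible(
            b_orig_sign, b_deriv_sign
        )
        return not kept
    negated = signs_compatible(
        a_orig_sign, a_deriv_sign, negated=True
    ) and signs_compatible(b_orig_sign, b_deriv_sign, negated=True)
    return not negated


def _index_children(x: PQNode) -> dict[int, int]:
    return {c.color: i for i, c in enumerate(x.children)}


def changed_signed_order(x: PQNode, x_ordered: PQNode, color_a: int, color_b: int) -> bool:
    """Whether the two children of ``x`` changed their signed order in
    ``x_ordered`` (both must survive there)."""
    orig_idx = _index_children(x)
    deriv_idx = _index_children(x_ordered)
    for col in (color_a, color_b):
        if col not in orig_idx:
            raise ValueError(f"color {col} is not a child of the original node")
        if col not in deriv_idx:
            raise ValueError(f"color {col} does not survive in the ordered node")
    by_color_orig = {c.color: c for c in x.children}
    by_color_deriv = {c.color: c for c in x_ordered.children}
    order_preserved = (orig_idx[color_a] < orig_idx[color_b]) == (
        deriv_idx[color_a] < deriv_idx[color_b]
    )
    return pair_changed_signed_order(
        order_preserved,
        node_sign(by_color_orig[color_a]),
        node_sign(by_color_deriv[color_a]),
        node_sign(by_color_orig[color_b]),
        node_sign(by_color_deriv[color_b]),
    )


def jump_graph_from_entries(
    entries: Sequence[tuple[Hashable, int, int, object, object, Fraction]],
) -> nx.Graph:
    """Build a jump graph from explicit per-child records.

    Each entry is ``(key, orig_index, derived_index, orig_sign,
    derived_sign, weight)``; signs may be scalars or sign sets.
    """
    g = nx.Graph()
    for key, _oi, _di, _os, _ds, weight in entries:
        g.add_node(key, weight=Fraction(weight))
    for i, (ka, oa, da, sa_o, sa_d, _wa) in enumerate(entries):
        for kb, ob, db, sb_o, sb_d, _wb in entries[i + 1 :]:
            order_preserved = (oa < ob) == (da < db)
            if pair_changed_signed_order(order_preserved, sa_o, sa_d, sb_o, sb_d):
                g.add_edge(ka, kb)
    return g


def build_jump_graph(x: PQNode, x_ordered: PQNode) -> nx.Graph:
    """Jump graph G[x, x'] of a P-node and its derived copy.

    Vertices are the children of ``x`` that survive in ``x_ordered`` (keyed
    by color, weighted by (span-1)/2 of the original child); edges join
    pairs that changed their signed order, with tie signs acting as
    whichever sign avoids an edge.
    """
    if x.kind != "P":
        raise ValueError(f"jump graphs are defined for P-nodes, got {x.kind}")
    deriv_idx = _index_children(x_ordered)
    by_color_deriv = {c.color: c for c in x_ordered.children}
    entries = []
    for oi, c in enumerate(x.children):
        if c.color not in deriv_idx:
            continue  # deleted child: no vertex
        entries.append(
            (
                c.color,
                oi,
                deriv_idx[c.color],
                node_sign(c),
                node_sign(by_color_deriv[c.color]),
                jump_weight(c.span),
            )
        )
    return jump_graph_from_entries(entries)


def min_weight_vertex_cover(g: nx.Graph) -> tuple[Fraction, frozenset]:
    """Exact minimum weight vertex cover.

    Branch and bound on the highest-degree vertex.  Deterministic
    tie-break: the lexicographically smallest sorted vertex set among the
    optima.
    """
    weights = {v: Fraction(g.nodes[v].get("weight", 1)) for v in g.nodes}

    def ordered(vs) -> tuple:
        try:
            return tuple(sorted(vs))
        except TypeError:
            return tuple(sorted(vs, key=repr))

    def solve(edges: frozenset[frozenset]) -> tuple[Fraction, tuple]:
        if not edges:
            return Fraction(0), ()
        degree: dict = {}
        for e in edges:
            for v in e:
                degree[v] = degree.get(v, 0) + 1
        pivot = min(ordered(degree), key=lambda v: -degree[v])
        # branch 1: pivot in the cover
        rest1 = frozenset(e for e in edges if pivot not in e)
        w1, c1 = solve(rest1)
        best = (w1 + weights[pivot], ordered(set(c1) | {pivot}))
        # branch 2: pivot not in the cover -> all its neighbours are
        neighbours = {v for e in edges if pivot in e for v in e if v != pivot}
        rest2 = frozenset(e for e in edges if not (e & neighbours))
        w2, c2 = solve(rest2)
        cand = (w2 + sum(weights[v] for v in neighbours), ordered(set(c2) | neighbours))
        if cand < best:
            best = cand
        return best

    edges = frozenset(frozenset((u, v)) for u, v in g.edges)
    weight, cover = solve(edges)
    return weight, frozenset(cover)


def min_vertex_cover_weight(
    entries: Sequence[tuple[Hashable, int, int, object, object, Fraction]],
) -> Fraction:
    """Minimum cover weight of the jump graph built from ``entries``."""
    weight, _ = min_weight_vertex_cover(jump_graph_from_entries(entries))
    return weight


def jump_violation(x: PQNode, x_ordered: PQNode) -> Fraction:
    """The jump violation of a P-node reordering: the minimum weight of a
    vertex cover of G[x, x']."""
    weight, _ = min_weight_vertex_cover(build_jump_graph(x, x_ordered))
    return weight
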