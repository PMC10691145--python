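"""Seeded synthetic instances: random PQ-trees and mutated targets.

The generator emulates the derivation semantics of the divergence model:
a target gene order is produced from a tree by legal reordering events
(P-node shuffles, Q-node/leaf flips), plus optional leaf deletions and
foreign-gene insertions that create instances requiring the deletion
budgets.  Every draw is reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .pqtree import LEAF, MINUS, P, PLUS, PQNode, PQTree, Q, SignedString

__all__ = ["GeneratorParams", "random_pqtree", "mutate_to_target"]


@dataclass
class GeneratorParams:
    """Knobs of the synthetic instance generator.

    Defaults describe a small, well-structured prokaryotic gene cluster:
    4-7 genes, balanced mix of colinear (Q) and order-free (P) sub-operons,
    out-degree at most 4, with roughly a third of the genes on the reverse
    strand.  Mutation counts define the rearrangement scenario applied to
    produce the target order.
    """

    min_leaves: int = 4
    max_leaves: int = 7
    p_node_prob: float = 0.5
    max_children: int = 4
    neg_leaf_prob: float = 0.3
    n_flips: int = 1
    n_p_shuffles: int = 1
    n_leaf_deletions: int = 0
    n_insertions: int = 0
    seed: int = 0


def _build(rng: random.Random, n_leaves: int, params: GeneratorParams,
           labels: list[str]) -> PQNode:
    if n_leaves == 1:
        lab = labels.pop()
        sign = MINUS if rng.random() < params.neg_leaf_prob else PLUS
        return PQNode(kind=LEAF, label=lab, leaf_sign=sign)
    arity = rng.randint(2, min(params.max_children, n_leaves))
    # partition n_leaves into `arity` positive parts
    cuts = sorted(rng.sample(range(1, n_leaves), arity - 1))
    parts = [b - a for a, b in zip([0] + cuts, cuts + [n_leaves])]
    kind = P if rng.random() < params.p_node_prob else Q
    return PQNode(kind=kind, children=[
        _build(rng, p, params, labels) for p in parts
    ])


def random_pqtree(params: GeneratorParams,
                  rng: Optional[random.Random] = None) -> PQTree:
    """A random valid PQ-tree within the parameter bounds."""
    rng = rng or random.Random(params.seed)
    n = rng.randint(params.min_leaves, params.max_leaves)
    labels = [f"g{k}" for k in range(n)]
    rng.shuffle(labels)
    return PQTree(_build(rng, n, params, labels))


def _flip_subtree(x: PQNode) -> None:
    """Structural flip: reverse every child list, negate every leaf sign."""
    if x.is_leaf():
        x.leaf_sign = -x.leaf_sign
        return
    x.children.reverse()
    for c in x.children:
        _flip_subtree(c)


def _prune(x: PQNode, deleted: set[int]) -> Optional[PQNode]:
    if x.is_leaf():
        return None if x.color in deleted else x
    kept = [c2 for c in x.children if (c2 := _prune(c, deleted)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    x.children = kept
    return x


def mutate_to_target(
    tree: PQTree,
    params: GeneratorParams,
    rng: Optional[random.Random] = None,
) -> tuple[SignedString, dict]:
    """Derive a target gene order from the tree by logged mutation events.

    Returns ``(target, log)``.  The target is derivable from the tree with
    ``d_T`` = number of logged leaf deletions and ``d_S`` = number of
    logged insertions.
    """
    rng = rng or random.Random(params.seed)
    work = tree.root.copy()
    log: dict = {"p_shuffles": [], "flips": [], "leaf_deletions": [],
                 "insertions": []}

    p_nodes = [v for v in work.iter_preorder() if v.kind == P]
    for _ in range(params.n_p_shuffles):
        if not p_nodes:
            break
        x = rng.choice(p_nodes)
        order = list(range(len(x.children)))
        rng.shuffle(order)
        x.children = [x.children[k] for k in order]
        log["p_shuffles"].append({"node": x.color, "order": order})

    flippable = [v for v in work.iter_preorder() if v.is_leaf() or v.kind == Q]
    for _ in range(params.n_flips):
        if not flippable:
            break
        x = rng.choice(flippable)
        _flip_subtree(x)
        log["flips"].append({"node": x.color})

    leaves = work.leaves()
    k_del = min(params.n_leaf_deletions, max(0, len(leaves) - 1))
    deleted = set()
    if k_del:
        chosen = rng.sample(leaves, k_del)
        deleted = {v.color for v in chosen}
        log["leaf_deletions"] = [
            {"color": v.color, "label": v.label} for v in chosen
        ]
        work = _prune(work, deleted)

    tokens = [(v.label, v.leaf_sign) for v in work.leaves()] if work else []
    for k in range(params.n_insertions):
        pos = rng.randint(0, len(tokens))
        sign = MINUS if rng.random() < params.neg_leaf_prob else PLUS
        tokens.insert(pos, (f"ins{k}", sign))
        log["insertions"].append({"position": pos + 1, "label": f"ins{k}"})

    return SignedString(tokens), log
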