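"""Brute-force reference implementation of the divergence.

Enumerates every derivation explicitly — all leaf-deletion subsets, all
orderings of the pruned tree (child permutations of P-nodes, both
orientations of Q-nodes), and all embeddings of the resulting frontier
into the target string within the string-deletion budget — and scores each
candidate by direct application of the per-node violation definitions.
Exponential and intended for small fixtures only; serves as the oracle the
dynamic-programming engines are verified against.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterator, Optional, Sequence

from .config import DivergenceResult, PenaltyConfig
from .pqtree import PLUS, PQNode, PQTree, Q, SignedString, node_sign, sign_from_pos
from .scoring import ChildRecord, p_node_violation, q_node_violation

__all__ = ["brute_force_diverge", "OracleSizeError"]


class OracleSizeError(ValueError):
    """Instance exceeds the brute-force size guard."""


# An arrangement is a nested tuple: leaves appear as the PQNode itself,
# internal nodes as (PQNode, (child_arrangement, ...)) in derived order.


def _arrangements(x: PQNode, deleted: frozenset[int]) -> Iterator[object]:
    if x.is_leaf():
        yield x
        return
    surv = [c for c in x.children
            if any(v.color not in deleted for v in c.leaves())]
    child_options = [list(_arrangements(c, deleted)) for c in surv]
    if not child_options:
        return
    if x.kind == Q:
        for combo in itertools.product(*child_options):
            yield (x, tuple(combo))
            if len(combo) > 1:
                yield (x, tuple(reversed(combo)))
    else:
        for perm in itertools.permutations(range(len(child_options))):
            for combo in itertools.product(
                *(child_options[i] for i in perm)
            ):
                yield (x, tuple(combo))


def _frontier_leaves(arr) -> list[PQNode]:
    if isinstance(arr, PQNode):
        return [arr]
    _, children = arr
    out: list[PQNode] = []
    for c in children:
        out.extend(_frontier_leaves(c))
    return out


def _embeddings(
    labels: Sequence[str], s2: SignedString, d_s: int
) -> Iterator[tuple[int, ...]]:
    """Strictly increasing 1-based positions matching ``labels`` whose
    window contains at most ``d_s`` unmatched characters."""
    n = len(s2)
    q = len(labels)
    if q == 0:
        yield ()
        return
    positions = {lab: [i for i in range(1, n + 1) if s2.label(i) == lab]
                 for lab in set(labels)}

    def rec(k: int, prev: int, first: int, acc: list[int]):
        if k == q:
            yield tuple(acc)
            return
        lab = labels[k]
        for p in positions[lab]:
            if p <= prev:
                continue
            # unmatched characters inside the window so far never shrink
            if first and (p - first + 1) - (k + 1) > d_s:
                continue
            acc.append(p)
            yield from rec(k + 1, p, first or p, acc)
            acc.pop()

    yield from rec(0, 0, 0, [])


def _score_arrangement(
    arr,
    deleted: frozenset[int],
    leaf_positions: dict[int, int],
    s2: SignedString,
    penalties: PenaltyConfig,
) -> tuple[Fraction, int, bool]:
    """Score one ordered, embedded derivation.

    Returns (score excluding deletion penalties, positive-leaf count,
    flipped-as-unit flag) for the subtree of ``arr``.
    """
    if isinstance(arr, PQNode):
        p = leaf_positions[arr.color]
        sg = s2.sign(p)
        flipped = sg == -arr.leaf_sign
        sc = penalties.delta_q_flip if flipped else Fraction(0)
        return sc, (1 if sg == PLUS else 0), flipped

    x, children = arr
    total = Fraction(0)
    infos = []
    for child_arr in children:
        sc, pos, flipped = _score_arrangement(
            child_arr, deleted, leaf_positions, s2, penalties
        )
        total += sc
        node = child_arr if isinstance(child_arr, PQNode) else child_arr[0]
        infos.append((node, pos, flipped))

    surv_orig = [c for c in x.children
                 if any(v.color not in deleted for v in c.leaves())]
    orig_index = {c.color: i for i, c in enumerate(surv_orig)}
    surv_count = {
        c.color: sum(1 for v in c.leaves() if v.color not in deleted)
        for c in surv_orig
    }
    records = []
    for di, (node, pos, flipped) in enumerate(infos):
        records.append(
            ChildRecord(
                key=node.color,
                orig_index=orig_index[node.color],
                deriv_index=di,
                orig_sign=node_sign(node),
                deriv_sign=sign_from_pos(pos, surv_count[node.color]),
                span=node.span,
                flipped=flipped,
                refundable=node.is_leaf() or node.kind == Q,
            )
        )
    deriv_order = [orig_index[node.color] for node, _, _ in infos]
    reversed_order = deriv_order == list(range(len(infos) - 1, -1, -1))
    node_flipped = reversed_order and all(f for _, _, f in infos)

    if x.kind == Q:
        violation, _, _, _ = q_node_violation(records, node_flipped, penalties)
    else:
        violation, _, _ = p_node_violation(records, penalties)
    total += violation
    return total, sum(p for _, p, _ in infos), node_flipped


def brute_force_diverge(
    tree: PQTree,
    s2: SignedString,
    d_t: int = 0,
    d_s: int = 0,
    penalties: PenaltyConfig = PenaltyConfig(),
    max_leaves: int = 8,
) -> DivergenceResult:
    """Exhaustive minimum-divergence search on a small instance."""
    if d_t < 0 or d_s < 0:
        raise ValueError("deletion budgets must be non-negative")
    leaves = tree.leaves()
    if len(leaves) > max_leaves or len(s2) > max_leaves + max(d_s, 2) + 2:
        raise OracleSizeError(
            f"instance too large for brute force ({len(leaves)} leaves, "
            f"|S2|={len(s2)})"
        )

    best: Optional[tuple[Fraction, dict]] = None
    leaf_colors = [v.color for v in leaves]
    for k in range(min(d_t, len(leaf_colors)) + 1):
        for del_combo in itertools.combinations(leaf_colors, k):
            deleted = frozenset(del_combo)
            if len(deleted) == len(leaf_colors):
                # fully deleted tree: empty frontier, empty window
                cand = penalties.rho_t_del * k
                meta = {"del_t": k, "del_s": 0, "start": None, "end": None}
                if best is None or cand < best[0]:
                    best = (cand, meta)
                continue
            seen = set()
            for arr in _arrangements(tree.root, deleted):
                fl = _frontier_leaves(arr)
                key = tuple(v.color for v in fl), _shape_key(arr)
                if key in seen:
                    continue
                seen.add(key)
                labels = [v.label for v in fl]
                for emb in _embeddings(labels, s2, d_s):
                    window_del = (emb[-1] - emb[0] + 1) - len(emb)
                    if window_del > d_s:
                        continue
                    leaf_positions = {
                        v.color: p for v, p in zip(fl, emb)
                    }
                    sc, _, _ = _score_arrangement(
                        arr, deleted, leaf_positions, s2, penalties
                    )
                    cand = (
                        sc
                        + penalties.rho_t_del * k
                        + penalties.rho_s_del * window_del
                    )
                    meta = {
                        "del_t": k,
                        "del_s": window_del,
                        "start": emb[0],
                        "end": emb[-1],
                    }
                    if best is None or cand < best[0]:
                        best = (cand, meta)

    if best is None:
        return DivergenceResult.no()
    score, meta = best
    return DivergenceResult(
        score=score,
        del_t=meta["del_t"],
        del_s=meta["del_s"],
        start=meta["start"],
        end=meta["end"],
    )


def _shape_key(arr) -> object:
    if isinstance(arr, PQNode):
        return arr.color
    x, children = arr
    return (x.color, tuple(_shape_key(c) for c in children))
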