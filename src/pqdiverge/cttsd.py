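"""Constrained tree-to-string divergence (permutations, no deletions).

Both the tree frontier and the target are signed permutations over the
same alphabet.  Because gene identifiers are unique and deletions are
forbidden, every node of the tree derives a unique substring of the target
(if any): leaves anchor at the position of their label, and internal nodes
must tile the intervals of their children contiguously — in any order for
a P-node, in the given or reversed order for a Q-node.  The divergence is
the sum over nodes of the reordering penalties:

* a leaf whose strand differs from its target character pays delta_q_flip;
* a P-node pays the signed break-point count between its original and
  derived child orders plus the jump violation (minimum weight vertex
  cover of the changed-signed-order graph);
* a Q-node pays delta_q_ord per signed break-point, plus delta_q_flip if
  it flipped as a unit, minus the flip correction refunding its children's
  flip penalties in that case.
"""

from __future__ import annotations

from fractions import Fraction

from .config import DivergenceResult, PenaltyConfig
from .pqtree import (
    PLUS,
    PQTree,
    Q,
    SignedString,
    frontier,
    node_sign,
    sign_from_pos,
)
from .scoring import ChildRecord, p_node_violation, q_node_violation

__all__ = ["cttsd_diverge"]


def _validate(tree: PQTree, s2: SignedString) -> None:
    ref = frontier(tree)
    if len(ref) != len(s2):
        raise ValueError(
            f"target length {len(s2)} differs from leaf count {len(ref)}"
        )
    ref_labels = sorted(ref.labels())
    tgt_labels = sorted(s2.labels())
    if len(set(ref_labels)) != len(ref_labels):
        raise ValueError("reference gene order is not a permutation "
                         "(duplicate gene ids)")
    if len(set(tgt_labels)) != len(tgt_labels):
        raise ValueError("target gene order is not a permutation "
                         "(duplicate gene ids)")
    if ref_labels != tgt_labels:
        raise ValueError("reference and target are over different alphabets")


def cttsd_diverge(
    tree: PQTree,
    s2: SignedString,
    penalties: PenaltyConfig = PenaltyConfig(),
    trace: bool = False,
) -> DivergenceResult:
    """Divergence from an ordered PQ-tree to a signed permutation.

    Returns a result whose ``score`` is the divergence, or an infeasible
    result when the target cannot be derived from the tree.  With
    ``trace=True`` the result carries, per node color, the resolved
    interval (1-based, inclusive) and the violation terms.
    """
    _validate(tree, s2)
    n = len(s2)
    pos_of = {s2.label(i): i for i in range(1, n + 1)}

    interval: dict[int, tuple[int, int]] = {}
    score: dict[int, Fraction] = {}
    flipped: dict[int, bool] = {}
    pos_count: dict[int, int] = {}  # positive-signed mapped leaves below node
    node_trace: dict[int, dict] = {}

    for x in tree.root.iter_postorder():
        if x.is_leaf():
            ell = pos_of[x.label]
            interval[x.color] = (ell, ell)
            tgt_sign = s2.sign(ell)
            flipped[x.color] = tgt_sign == -x.leaf_sign
            score[x.color] = (
                penalties.delta_q_flip if flipped[x.color] else Fraction(0)
            )
            pos_count[x.color] = 1 if tgt_sign == PLUS else 0
            if trace:
                node_trace[x.color] = {
                    "kind": "LEAF",
                    "label": x.label,
                    "start": ell,
                    "end": ell,
                    "score": score[x.color],
                }
            continue

        ivs = [interval[c.color] for c in x.children]
        order = sorted(range(len(ivs)), key=lambda k: ivs[k][0])
        ell = ivs[order[0]][0]
        r = ivs[order[-1]][1]
        ok = all(
            ivs[order[k]][1] + 1 == ivs[order[k + 1]][0]
            for k in range(len(order) - 1)
        )
        if x.kind == Q and ok:
            ok = order == list(range(len(ivs))) or order == list(
                range(len(ivs) - 1, -1, -1)
            )
        if not ok:
            return DivergenceResult.no()

        interval[x.color] = (ell, r)
        pos_count[x.color] = sum(pos_count[c.color] for c in x.children)
        deriv_index = {order[k]: k for k in range(len(order))}
        records = []
        for idx, c in enumerate(x.children):
            records.append(
                ChildRecord(
                    key=c.color,
                    orig_index=idx,
                    deriv_index=deriv_index[idx],
                    orig_sign=node_sign(c),
                    deriv_sign=sign_from_pos(pos_count[c.color], c.span),
                    span=c.span,
                    flipped=flipped[c.color],
                    refundable=c.is_leaf() or c.kind == Q,
                )
            )
        children_dist = sum((score[c.color] for c in x.children), Fraction(0))
        reversed_order = order == list(range(len(ivs) - 1, -1, -1))
        node_flipped = reversed_order and all(flipped[c.color] for c in x.children)
        flipped[x.color] = node_flipped

        if x.kind == Q:
            violation, bp, flip_pen, correction = q_node_violation(
                records, node_flipped, penalties
            )
            jump = Fraction(0)
        else:
            violation, bp, jump = p_node_violation(records, penalties)
            flip_pen = Fraction(0)
            correction = Fraction(0)
        score[x.color] = children_dist + violation
        if trace:
            node_trace[x.color] = {
                "kind": x.kind,
                "start": ell,
                "end": r,
                "children_dist": children_dist,
                "d_sbp": bp,
                "jump": jump,
                "flip_penalty": flip_pen,
                "flip_correction": correction,
                "violation": violation,
                "score": score[x.color],
            }

    root = tree.root
    if interval[root.color] != (1, n):
        return DivergenceResult.no()
    return DivergenceResult(
        score=score[root.color],
        start=1,
        end=n,
        node_trace=node_trace,
    )
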