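"""Shared per-node violation scoring.

Both the constrained engine and the brute-force reference scorer reduce a
derivation to, per internal node, a small record per surviving child:
original index, derived index, original majority sign (a set when tied),
derived majority sign (a set when tied), whether the child flipped as a
unit, original span, and whether it is refundable (leaf or Q-node).  The
functions here turn such records into the node's violation.

Sign ties are resolved by minimization over one consistent sign choice per
child within the node (matching the general engine, which commits to a
single sign per child derivation); the original side is compared
set-tolerantly pair by pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .breakpoints import count_signed_breakpoints_unique
from .config import PenaltyConfig
from .jump import jump_graph_from_entries, jump_weight, min_weight_vertex_cover

__all__ = ["ChildRecord", "p_node_violation", "q_node_violation"]


@dataclass(frozen=True)
class ChildRecord:
    key: object                 # child color
    orig_index: int             # position among surviving children, original order
    deriv_index: int            # position among surviving children, derived order
    orig_sign: frozenset        # majority sign in the original tree (tie = both)
    deriv_sign: frozenset       # majority sign in the derivation (tie = both)
    span: int                   # original span (all leaves, incl. later-deleted)
    flipped: bool               # the child flipped as a unit in the derivation
    refundable: bool            # leaf or Q-node (carries its own flip penalty)


def _sign_assignments(children: Sequence[ChildRecord]):
    """All consistent derived-sign choices (ties branch, scalars do not)."""
    choices = [sorted(c.deriv_sign, reverse=True) for c in children]
    return itertools.product(*choices)


def _breakpoints(children: Sequence[ChildRecord], signs) -> int:
    orig = sorted(zip(children, signs), key=lambda t: t[0].orig_index)
    deriv = sorted(zip(children, signs), key=lambda t: t[0].deriv_index)
    return count_signed_breakpoints_unique(
        [(c.key, c.orig_sign) for c, _ in orig],
        [(c.key, s) for c, s in deriv],
    )


def p_node_violation(
    children: Sequence[ChildRecord], penalties: PenaltyConfig
) -> tuple[Fraction, int, Fraction]:
    """P-node violation: signed break-points plus the jump cover weight.

    Returns ``(total, breakpoints, jump)`` for the minimizing sign
    assignment (ties in the total broken toward the first assignment
    enumerated, positive sign first).
    """
    best = None
    for signs in _sign_assignments(children):
        bp = _breakpoints(children, signs)
        if penalties.jump_enabled:
            entries = [
                (c.key, c.orig_index, c.deriv_index, c.orig_sign,
                 frozenset((s,)), jump_weight(c.span))
                for c, s in zip(children, signs)
            ]
            jump, _ = min_weight_vertex_cover(jump_graph_from_entries(entries))
        else:
            jump = Fraction(0)
        total = Fraction(bp) + jump
        if best is None or total < best[0]:
            best = (total, bp, jump)
    if best is None:  # no surviving children
        return Fraction(0), 0, Fraction(0)
    return best


def q_node_violation(
    children: Sequence[ChildRecord],
    node_flipped: bool,
    penalties: PenaltyConfig,
) -> tuple[Fraction, int, Fraction, Fraction]:
    """Q-node violation with the flip event and its correction.

    Returns ``(total, breakpoints, flip_penalty, flip_correction)`` where
    ``total = delta_q_ord * breakpoints + flip_penalty - flip_correction``.
    The flip event is mandatory: a node whose surviving children appear in
    reversed order, all flipped, pays ``delta_q_flip`` once and is refunded
    the flip penalties of its surviving leaf and Q-node children.
    """
    best_bp = None
    for signs in _sign_assignments(children):
        bp = _breakpoints(children, signs)
        if best_bp is None or bp < best_bp:
            best_bp = bp
    if best_bp is None:
        best_bp = 0
    flip_pen = Fraction(0)
    correction = Fraction(0)
    if node_flipped:
        flip_pen = penalties.delta_q_flip
        correction = penalties.delta_q_flip * sum(1 for c in children if c.refundable)
    total = penalties.delta_q_ord * best_bp + flip_pen - correction
    return total, best_bp, flip_pen, correction
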