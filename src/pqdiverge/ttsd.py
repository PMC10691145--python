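"""General tree-to-string divergence with deletions.

Dynamic program over the PQ-tree in postorder.  For every node x, start
index i in the target, deletion counts (k_T from the tree, k_S from the
string) and positive-leaf count pos, the table holds the minimum
divergence of a derivation of the subtree T_x to the window
S2[i : i-1+span(x)-k_T+k_S] — the window is derived, not stored.  Internal
nodes are filled by a P-mapping (subsets of children in any order) or a
Q-mapping (two directional scans), supporting whole-child deletions at
rho_t_del per leaf, character deletions at rho_s_del, and signed
break-point charges between consecutive surviving children.

Every node keeps two surfaces: the minimum over derivations in which the
node did *not* flip as a unit, and the minimum over derivations in which
it did (surviving children in reversed order, each flipped).  The flipped
surface of a Q-node pays delta_q_flip and is refunded the flip penalties
of its surviving leaf and Q-node children; parents consume the two
surfaces separately so that the flip event is charged exactly per the
divergence definition.

The final answer minimizes over all root entries (all windows, budgets
and positive-leaf counts): characters outside the chosen window are not
charged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Optional

from .config import DivergenceResult, PenaltyConfig
from .jump import jump_weight, pair_changed_signed_order
from .pqtree import (
    MINUS,
    PLUS,
    PQNode,
    PQTree,
    Q,
    SignedString,
    node_sign,
    sign_from_pos,
)

__all__ = [
    "ttsd_diverge",
    "ChildDeriv",
    "build_child_index",
    "length_fn",
    "end_fn",
    "bp_delta",
    "bp_delta2",
    "jump_violation_delta",
]


def length_fn(x: PQNode, k_t: int, k_s: int) -> int:
    """Length of the string derived from ``x`` with the given deletions:
    span(x) - k_T + k_S."""
    if k_t > x.span:
        raise ValueError("cannot delete more leaves than the node spans")
    return x.span - k_t + k_s


def end_fn(x: PQNode, start: int, k_t: int, k_s: int) -> int:
    """End position of a derivation starting at ``start`` (1-based,
    inclusive): start - 1 + L(x, k_T, k_S)."""
    return start - 1 + length_fn(x, k_t, k_s)


def bp_delta(x: PQNode, y: PQNode, z: PQNode, neg_colors) -> int:
    """0 iff ``y`` and ``z`` are adjacent children of ``x`` and, placed
    consecutively in that order in the derivation with the signs given by
    ``neg_colors`` (set of colors with negative derived sign), did not
    change their signed order; else 1."""
    idx = {c.color: k for k, c in enumerate(x.children)}
    iy, iz = idx[y.color], idx[z.color]
    if abs(iy - iz) != 1:
        return 1
    return bp_delta2(x, y, z, neg_colors)


def bp_delta2(x: PQNode, y: PQNode, z: PQNode, neg_colors) -> int:
    """Like :func:`bp_delta` but without the adjacency requirement (used
    when the children between ``y`` and ``z`` are all deleted)."""
    idx = {c.color: k for k, c in enumerate(x.children)}
    iy, iz = idx[y.color], idx[z.color]
    s_y = frozenset((MINUS,)) if y.color in neg_colors else frozenset((PLUS,))
    s_z = frozenset((MINUS,)) if z.color in neg_colors else frozenset((PLUS,))
    changed = pair_changed_signed_order(
        iy < iz, node_sign(y), s_y, node_sign(z), s_z
    )
    return 1 if changed else 0


def jump_violation_delta(cover_colors, x: PQNode) -> Fraction:
    """(span(x) - 1) / 2 if ``x`` is in the candidate cover, else 0."""
    if x.color in cover_colors:
        return jump_weight(x.span)
    return Fraction(0)


@dataclass(frozen=True)
class ChildDeriv:
    """One stored derivation of a child, in window-relative coordinates."""

    rel_start: int
    rel_end: int
    k_t: int
    k_s: int
    pos: int
    sign: int          # committed derived majority sign (ties expand)
    score: Fraction
    flipped: bool      # drawn from the flipped surface


Tables = dict[int, dict[tuple, Fraction]]  # color -> {(pos, i, k_t, k_s): score}


def _merge_min(d: dict, key, value) -> None:
    old = d.get(key)
    if old is None or value < old:
        d[key] = value


def build_child_index(
    c: PQNode,
    i_abs: int,
    win_len: int,
    an: Tables,
    af: Tables,
) -> dict[int, list[ChildDeriv]]:
    """Index a child's stored derivations by window-relative start."""
    out: dict[int, list[ChildDeriv]] = defaultdict(list)
    for table, flipped in ((an, False), (af, True)):
        for (pos, i2, kt, ks), sc in table.get(c.color, {}).items():
            if i2 < i_abs:
                continue
            rel_start = i2 - i_abs + 1
            rel_end = rel_start + (c.span - kt + ks) - 1
            if rel_end > win_len:
                continue
            for s in sorted(sign_from_pos(pos, c.span - kt), reverse=True):
                out[rel_start].append(
                    ChildDeriv(rel_start, rel_end, kt, ks, pos, s, sc, flipped)
                )
    return out


# ---------------------------------------------------------------------------
# P-mapping
# ---------------------------------------------------------------------------

def p_mapping(
    x: PQNode,
    i_abs: int,
    win_len: int,
    child_index: list[dict[int, list[ChildDeriv]]],
    d_t: int,
    d_s: int,
    penalties: PenaltyConfig,
) -> tuple[dict, dict]:
    """Derivations of a P-node to prefixes of the window.

    Returns ``(out_not_flipped, out_flipped)`` keyed ``(pos, k_t, k_s)``.
    State: which children are mapped / deleted, the last mapped child and
    its committed sign, the set U of mapped children left outside the
    vertex cover (with their signs), deletion counts, positive-leaf count,
    and whether the partial derivation is still an exact reversal built
    from flipped children.
    """
    children = x.children
    g = len(children)
    spans = [c.span for c in children]
    orig_signs = [node_sign(c) for c in children]
    full_mask = (1 << g) - 1
    span_of_mask = [0] * (1 << g)
    for m in range(1, 1 << g):
        low = (m & -m).bit_length() - 1
        span_of_mask[m] = span_of_mask[m & (m - 1)] + spans[low]
    betw = [[0] * g for _ in range(g)]
    for a in range(g):
        for b in range(g):
            lo, hi = min(a, b), max(a, b)
            mask = 0
            for k in range(lo + 1, hi):
                mask |= 1 << k
            betw[a][b] = mask

    jump_on = penalties.jump_enabled
    rho_t = penalties.rho_t_del
    rho_s = penalties.rho_s_del

    # levels[popcount][k_s] : {state: score}
    levels: list[dict[int, dict]] = [defaultdict(dict) for _ in range(g + 1)]

    def push(state, score):
        mapped, deleted, *_rest, k_t, k_s, _pos, _flag = state
        used = mapped | deleted
        _merge_min(levels[bin(used).count("1")][k_s], state, score)

    def cover_choices(z: int, s_z: int, u_set: frozenset):
        """Ways to account child z in the jump cover."""
        if not jump_on:
            yield Fraction(0), u_set
            return
        yield jump_weight(spans[z]), u_set  # z joins the cover
        for u_idx, u_s in u_set:  # z stays out: no edge to any uncovered
            if pair_changed_signed_order(
                (u_idx < z) is True,  # derived: u before z
                orig_signs[u_idx],
                frozenset((u_s,)),
                orig_signs[z],
                frozenset((s_z,)),
            ):
                return
        yield Fraction(0), u_set | {(z, s_z)}

    # init: first mapped child starts the window
    for z in range(g):
        for mu in child_index[z].get(1, ()):
            if mu.k_t > d_t or mu.k_s > d_s:
                continue
            for charge, u2 in cover_choices(z, mu.sign, frozenset()):
                state = (
                    1 << z, 0, z, mu.sign, u2,
                    mu.k_t, mu.k_s, mu.pos, mu.flipped,
                )
                push(state, mu.score + charge)

    out_plain: dict = {}
    out_flip: dict = {}

    for pop in range(1, g + 1):
        for k_s_round in range(d_s + 1):
            bucket = levels[pop][k_s_round]
            # items may be added to this bucket by case-1 from k_s_round-1
            for state, score in list(bucket.items()):
                (mapped, deleted, y, s_y, u_set,
                 k_t, k_s, pos, flag) = state
                used = mapped | deleted
                e_rel = span_of_mask[mapped] - (k_t - span_of_mask[deleted]) + k_s

                # completion: delete the unused children outright
                unused = full_mask & ~used
                extra = span_of_mask[unused]
                kt_tot = k_t + extra
                if kt_tot <= d_t:
                    target = out_flip if flag else out_plain
                    _merge_min(target, (pos, kt_tot, k_s), score + rho_t * extra)

                # case 1: delete the next window character
                if k_s + 1 <= d_s and e_rel + 1 <= win_len:
                    s1 = (mapped, deleted, y, s_y, u_set,
                          k_t, k_s + 1, pos, flag)
                    push(s1, score + rho_s)

                # append another mapped child, optionally bridging over a
                # deleted block of the children originally between
                for z in range(g):
                    if used >> z & 1:
                        continue
                    for mu in child_index[z].get(e_rel + 1, ()):
                        ks2 = k_s + mu.k_s
                        if ks2 > d_s:
                            continue
                        betw_mask = betw[y][z]
                        options = {0}
                        b_full = betw_mask & ~used
                        options.add(b_full)
                        for b in options:
                            kt2 = k_t + mu.k_t + span_of_mask[b]
                            if kt2 > d_t:
                                continue
                            deleted2 = deleted | b
                            signed_ok = not pair_changed_signed_order(
                                y < z,  # derived: y before z
                                orig_signs[y],
                                frozenset((s_y,)),
                                orig_signs[z],
                                frozenset((mu.sign,)),
                            )
                            bridged = (betw_mask & ~deleted2) == 0
                            bp = 0 if (signed_ok and bridged) else 1
                            base = (
                                score + mu.score + bp
                                + rho_t * span_of_mask[b]
                            )
                            flag2 = flag and mu.flipped and (z < y)
                            for charge, u2 in cover_choices(z, mu.sign, u_set):
                                s2 = (
                                    mapped | (1 << z), deleted2, z, mu.sign,
                                    u2, kt2, ks2, pos + mu.pos, flag2,
                                )
                                push(s2, base + charge)
    return out_plain, out_flip


# ---------------------------------------------------------------------------
# Q-mapping
# ---------------------------------------------------------------------------

def q_mapping(
    x: PQNode,
    i_abs: int,
    win_len: int,
    child_index: list[dict[int, list[ChildDeriv]]],
    d_t: int,
    d_s: int,
    penalties: PenaltyConfig,
) -> tuple[dict, dict]:
    """Derivations of a Q-node: two directional scans over the children.

    The forward scan realizes the given child order, the reverse scan the
    reversed order; children skipped by a scan step are deleted whole.
    Returns ``(out_not_flipped, out_flipped)`` keyed ``(pos, k_t, k_s)``.
    """
    children = x.children
    g = len(children)
    rho_t = penalties.rho_t_del
    rho_s = penalties.rho_s_del
    d_ord = penalties.delta_q_ord
    d_flip = penalties.delta_q_flip

    out_plain: dict = {}
    out_flip: dict = {}

    for direction in ("fwd", "rev"):
        if direction == "fwd":
            seq = list(range(g))
        else:
            seq = list(range(g - 1, -1, -1))
        seq_spans = [children[j].span for j in seq]
        prefix = [0]
        for sp in seq_spans:
            prefix.append(prefix[-1] + sp)
        orig_signs = [node_sign(children[j]) for j in seq]
        refundable = [children[j].is_leaf() or children[j].kind == Q for j in seq]
        order_preserved = direction == "fwd"

        # levels[last_index][k_s] : {state: score}
        levels: list[dict[int, dict]] = [defaultdict(dict) for _ in range(g)]

        def push(state, score):
            last, _s, _kt, k_s, _pos, _flag, _mc, _rf = state
            _merge_min(levels[last][k_s], state, score)

        for i0 in range(g):
            pre_span = prefix[i0]
            if pre_span > d_t:
                break
            for mu in child_index[seq[i0]].get(1, ()):
                kt = pre_span + mu.k_t
                if kt > d_t or mu.k_s > d_s:
                    continue
                state = (
                    i0, mu.sign, kt, mu.k_s, mu.pos, mu.flipped,
                    1, 1 if refundable[i0] else 0,
                )
                push(state, rho_t * pre_span + mu.score)

        for last in range(g):
            for k_s_round in range(d_s + 1):
                bucket = levels[last][k_s_round]
                for state, score in list(bucket.items()):
                    (_l, s_last, k_t, k_s, pos, flag, mcount, rcount) = state
                    e_rel = prefix[last + 1] - k_t + k_s

                    # completion: delete the suffix children
                    extra = prefix[g] - prefix[last + 1]
                    kt_tot = k_t + extra
                    if kt_tot <= d_t:
                        total = score + rho_t * extra
                        is_flip = flag and (direction == "rev" or mcount == 1)
                        if is_flip:
                            _merge_min(
                                out_flip,
                                (pos, kt_tot, k_s),
                                total + d_flip - d_flip * rcount,
                            )
                        else:
                            _merge_min(out_plain, (pos, kt_tot, k_s), total)

                    # case 1: delete the next window character
                    if k_s + 1 <= d_s and e_rel + 1 <= win_len:
                        push(
                            (last, s_last, k_t, k_s + 1, pos, flag,
                             mcount, rcount),
                            score + rho_s,
                        )

                    # extend to a later child, deleting the block between
                    for nxt in range(last + 1, g):
                        block = prefix[nxt] - prefix[last + 1]
                        for mu in child_index[seq[nxt]].get(e_rel + 1, ()):
                            kt2 = k_t + block + mu.k_t
                            ks2 = k_s + mu.k_s
                            if kt2 > d_t or ks2 > d_s:
                                continue
                            changed = pair_changed_signed_order(
                                order_preserved,
                                orig_signs[last],
                                frozenset((s_last,)),
                                orig_signs[nxt],
                                frozenset((mu.sign,)),
                            )
                            bp = 1 if changed else 0
                            push(
                                (
                                    nxt, mu.sign, kt2, ks2, pos + mu.pos,
                                    flag and mu.flipped, mcount + 1,
                                    rcount + (1 if refundable[nxt] else 0),
                                ),
                                score + mu.score + d_ord * bp + rho_t * block,
                            )
    return out_plain, out_flip


# ---------------------------------------------------------------------------
# Main algorithm
# ---------------------------------------------------------------------------

PMapper = Callable[..., tuple[dict, dict]]


def ttsd_diverge(
    tree: PQTree,
    s2: SignedString,
    d_t: int = 0,
    d_s: int = 0,
    penalties: PenaltyConfig = PenaltyConfig(),
    p_mapper: Optional[PMapper] = None,
) -> DivergenceResult:
    """Minimum divergence from the tree to a window of the target.

    Allows up to ``d_t`` leaf deletions from the tree (rho_t_del each) and
    ``d_s`` character deletions inside the chosen target window
    (rho_s_del each).  ``p_mapper`` optionally replaces the exact subset
    P-mapping (the polynomial-space engine hooks in here).
    """
    if d_t < 0 or d_s < 0:
        raise ValueError("deletion budgets must be non-negative")
    n = len(s2)
    mapper = p_mapper if p_mapper is not None else p_mapping

    an: Tables = defaultdict(dict)
    af: Tables = defaultdict(dict)

    for x in tree.root.iter_postorder():
        if x.is_leaf():
            for i in range(1, n + 1):
                for ks in range(d_s + 1):
                    if i + ks > n:
                        break
                    for j in range(i, i + ks + 1):
                        if s2.label(j) != x.label:
                            continue
                        sg = s2.sign(j)
                        pos = 1 if sg == PLUS else 0
                        flipped = sg == -x.leaf_sign
                        score = (
                            penalties.delta_q_flip if flipped else Fraction(0)
                        ) + penalties.rho_s_del * ks
                        table = af if flipped else an
                        _merge_min(table[x.color], (pos, i, 0, ks), score)
            continue

        span = x.span
        for i in range(1, n - (span - d_t) + 2):
            win_len = min(n - i + 1, span + d_s)
            if win_len < span - d_t:
                continue
            child_index = [
                build_child_index(c, i, win_len, an, af) for c in x.children
            ]
            if x.kind == Q:
                plain, flip = q_mapping(
                    x, i, win_len, child_index, d_t, d_s, penalties
                )
            else:
                plain, flip = mapper(
                    x, i, win_len, child_index, d_t, d_s, penalties
                )
            for (pos, kt, ks), sc in plain.items():
                _merge_min(an[x.color], (pos, i, kt, ks), sc)
            for (pos, kt, ks), sc in flip.items():
                _merge_min(af[x.color], (pos, i, kt, ks), sc)

    root = tree.root.color
    span = tree.root.span
    best = None
    for table in (an, af):
        for (pos, i, kt, ks), sc in table.get(root, {}).items():
            meta = (kt, ks, i, i - 1 + span - kt + ks)
            if best is None or sc < best[0]:
                best = (sc, meta)
    if span <= d_t:
        cand = penalties.rho_t_del * span
        if best is None or cand < best[0]:
            best = (cand, (span, 0, None, None))
    if best is None:
        return DivergenceResult.no()
    sc, (kt, ks, start, end) = best
    return DivergenceResult(score=sc, del_t=kt, del_s=ks, start=start, end=end)
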