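"""Polynomial-space P-node mapping via inclusion–exclusion.

Instead of tabulating subsets of a P-node's children, this engine *counts*
partial derivations.  A walk DP counts, per (deletions, positive-leaf
count, exact score), the derivation event sequences that use exactly
gamma child slots drawn from an allowed child set C with repetition; the
inclusion–exclusion alternating sum over excluded-children subsets Y then
isolates the sequences that use every child exactly once.  The divergence
per (k_T, k_S, pos) is the smallest score whose count is positive.

Scores are exact rationals used directly as sparse table keys, so the
score dimension (the ScoreSet) materializes as the reachable values;
counts are arbitrary-precision integers.  Valid only with the jump
penalty disabled: the vertex-cover bookkeeping of the subset DP has no
counting analogue here.
"""

from __future__ import annotations

from collections import defaultdict
from fractions import Fraction

from .config import PenaltyConfig
from .jump import pair_changed_signed_order
from .pqtree import PQNode, node_sign
from .ttsd import ChildDeriv

__all__ = ["internal_p_mapping_count", "p_mapping_inclusion_exclusion"]


def internal_p_mapping_count(
    x: PQNode,
    c_mask: int,
    win_len: int,
    child_index: list[dict[int, list[ChildDeriv]]],
    d_t: int,
    d_s: int,
    penalties: PenaltyConfig,
    flip_restricted: bool = False,
) -> dict[tuple, dict[Fraction, int]]:
    """Count derivation walks of length gamma over the children in c_mask.

    A walk appends events left to right over the window: map a child
    (consuming its stored derivation), map a child across a wholly deleted
    block of the children originally between, or delete a window
    character; unused slots are closed by flat child deletions at the end.
    Children may repeat — exactness is restored by inclusion–exclusion in
    the caller.  With ``flip_restricted`` only flipped child derivations
    appended in reversed original order are counted.

    Returns ``{(k_t, k_s, pos): {score: count}}`` for walks whose covered
    prefix length matches an exactly-once derivation.
    """
    children = x.children
    g = len(children)
    spans = [c.span for c in children]
    orig_signs = [node_sign(c) for c in children]
    span_all = sum(spans)
    rho_t = penalties.rho_t_del
    rho_s = penalties.rho_s_del

    betw = [[0] * g for _ in range(g)]
    betw_span = [[0] * g for _ in range(g)]
    for a in range(g):
        for b in range(g):
            lo, hi = min(a, b), max(a, b)
            mask = 0
            for k in range(lo + 1, hi):
                mask |= 1 << k
                betw_span[a][b] += spans[k]
            betw[a][b] = mask

    allowed = [z for z in range(g) if c_mask >> z & 1]

    def mus(z: int, rel_start: int):
        for mu in child_index[z].get(rel_start, ()):
            if flip_restricted and not mu.flipped:
                continue
            yield mu

    # table[slots][(y, s_y, e_rel, k_t, k_s, pos)] = {score: count}
    table: list[dict] = [defaultdict(lambda: defaultdict(int))
                         for _ in range(g + 1)]
    for z in allowed:
        for mu in mus(z, 1):
            if mu.k_t <= d_t and mu.k_s <= d_s:
                key = (z, mu.sign, mu.rel_end, mu.k_t, mu.k_s, mu.pos)
                table[1][key][mu.score] += 1

    # deletion-only walk starts are not needed: flat deletions commute with
    # every other event, so they are all accounted at completion.

    out: dict[tuple, dict[Fraction, int]] = defaultdict(lambda: defaultdict(int))

    deletable_subsets: dict[int, list[tuple[int, int]]] = defaultdict(list)
    # enumerate subsets of c_mask once, grouped by size: (mask, span)
    sub = c_mask
    while True:
        size = bin(sub).count("1")
        sp = sum(spans[z] for z in range(g) if sub >> z & 1)
        deletable_subsets[size].append((sub, sp))
        if sub == 0:
            break
        sub = (sub - 1) & c_mask

    for slots in range(1, g + 1):
        # close k_s within the level before expanding (case 1 keeps slots)
        for ks_round in range(d_s + 1):
            for key in [k for k in table[slots] if k[4] == ks_round]:
                y, s_y, e_rel, k_t, k_s, pos = key
                scores = table[slots][key]
                if k_s + 1 <= d_s and e_rel + 1 <= win_len:
                    nkey = (y, s_y, e_rel + 1, k_t, k_s + 1, pos)
                    tgt = table[slots][nkey]
                    for sc, cnt in scores.items():
                        tgt[sc + rho_s] += cnt

        for key, scores in table[slots].items():
            y, s_y, e_rel, k_t, k_s, pos = key

            # completion: delete a subset of children in the leftover slots
            want = g - slots
            for dmask, dspan in deletable_subsets.get(want, ()):
                kt_tot = k_t + dspan
                if kt_tot > d_t:
                    continue
                if e_rel != span_all - kt_tot + k_s:
                    continue
                okey = (kt_tot, k_s, pos)
                extra = rho_t * dspan
                tgt = out[okey]
                for sc, cnt in scores.items():
                    tgt[sc + extra] += cnt

            if slots == g:
                continue

            for z in allowed:
                if flip_restricted and z >= y:
                    continue
                for mu in mus(z, e_rel + 1):
                    ks2 = k_s + mu.k_s
                    if ks2 > d_s:
                        continue
                    signed_ok = not pair_changed_signed_order(
                        y < z,
                        orig_signs[y],
                        frozenset((s_y,)),
                        orig_signs[z],
                        frozenset((mu.sign,)),
                    )
                    # plain append: break-point unless originally adjacent
                    kt2 = k_t + mu.k_t
                    if kt2 <= d_t:
                        bp = 0 if (signed_ok and abs(z - y) == 1) else 1
                        nkey = (z, mu.sign, mu.rel_end, kt2, ks2,
                                pos + mu.pos)
                        tgt = table[slots + 1][nkey]
                        for sc, cnt in scores.items():
                            tgt[sc + mu.score + bp] += cnt
                    # bridging append: delete the whole between block
                    bmask = betw[y][z]
                    bsize = bin(bmask).count("1")
                    if bmask and (bmask & c_mask) == bmask:
                        kt3 = k_t + mu.k_t + betw_span[y][z]
                        if kt3 <= d_t and slots + 1 + bsize <= g:
                            bp = 0 if signed_ok else 1
                            nkey = (z, mu.sign, mu.rel_end, kt3, ks2,
                                    pos + mu.pos)
                            tgt = table[slots + 1 + bsize][nkey]
                            extra = mu.score + bp + rho_t * betw_span[y][z]
                            for sc, cnt in scores.items():
                                tgt[sc + extra] += cnt
    return out


def p_mapping_inclusion_exclusion(
    x: PQNode,
    i_abs: int,
    win_len: int,
    child_index: list[dict[int, list[ChildDeriv]]],
    d_t: int,
    d_s: int,
    penalties: PenaltyConfig,
) -> tuple[dict, dict]:
    """Drop-in replacement for the subset P-mapping, jump penalty disabled.

    For every excluded-children subset Y, counts walks avoiding Y; the
    alternating sum isolates exactly-once derivations.  Returns the two
    surfaces ``(out_not_flipped, out_flipped)`` keyed ``(pos, k_t, k_s)``
    with the minimum achievable score per key.
    """
    if penalties.jump_enabled:
        raise ValueError(
            "the inclusion-exclusion P-mapping requires the jump penalty "
            "to be disabled (pass jump_enabled=False)"
        )
    g = len(x.children)
    full = (1 << g) - 1

    total_general: dict[tuple, dict[Fraction, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    total_flip: dict[tuple, dict[Fraction, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for y_mask in range(full + 1):
        sign = -1 if bin(y_mask).count("1") % 2 else 1
        c_mask = full & ~y_mask
        for restricted, total in ((False, total_general), (True, total_flip)):
            counts = internal_p_mapping_count(
                x, c_mask, win_len, child_index, d_t, d_s, penalties,
                flip_restricted=restricted,
            )
            for key, per_score in counts.items():
                tgt = total[key]
                for sc, cnt in per_score.items():
                    tgt[sc] += sign * cnt

    out_plain: dict = {}
    out_flip: dict = {}
    for (kt, ks, pos), per_score in total_general.items():
        flip_scores = total_flip.get((kt, ks, pos), {})
        best_plain = None
        best_flip = None
        for sc in sorted(set(per_score) | set(flip_scores)):
            cnt = per_score.get(sc, 0)
            fcnt = flip_scores.get(sc, 0)
            if cnt < 0 or fcnt < 0 or cnt - fcnt < 0:
                raise AssertionError(
                    "inclusion-exclusion produced a negative derivation count"
                )
            if best_flip is None and fcnt > 0:
                best_flip = sc
            if best_plain is None and cnt - fcnt > 0:
                best_plain = sc
        if best_plain is not None:
            out_plain[(pos, kt, ks)] = best_plain
        if best_flip is not None:
            out_flip[(pos, kt, ks)] = best_flip
    return out_plain, out_flip
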