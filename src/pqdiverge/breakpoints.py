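"""Break-point distances between gene orders.

A gene mapping pairs every position of one string with a position of the
other carrying the same gene identifier.  A break-point is an adjacency of
one string that the mapping does not preserve in the other; the signed
variant additionally requires strand agreement (order-preserving pairs must
keep both signs, order-reversing pairs must negate both).  The distances
minimize the break-point count over all gene mappings; when all gene
identifiers are distinct the mapping is unique.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

from .pqtree import SignedString

__all__ = [
    "NoMappingError",
    "TooManyMappingsError",
    "enumerate_gene_mappings",
    "num_breakpoints",
    "breakpoint_distance",
    "num_signed_breakpoints",
    "signed_breakpoint_distance",
    "signed_pair_preserved",
    "count_signed_breakpoints_unique",
]

MAPPING_GUARD = 100_000


class NoMappingError(ValueError):
    """The two strings do not have identical gene-id multisets."""


class TooManyMappingsError(ValueError):
    """The exhaustive mapping enumeration would exceed the guard."""


def enumerate_gene_mappings(
    g: SignedString, h: SignedString
) -> Iterator[dict[int, int]]:
    """Yield all total gene mappings of ``g`` and ``h`` as dicts i -> j.

    Positions are 1-based.  Raises :class:`NoMappingError` if the gene-id
    multisets differ and :class:`TooManyMappingsError` beyond the guard
    (the enumeration is factorial in per-gene multiplicity; inside the
    divergence engines mappings are always unique because node colors are
    unique).
    """
    by_label_g: dict[str, list[int]] = {}
    by_label_h: dict[str, list[int]] = {}
    for i in range(1, len(g) + 1):
        by_label_g.setdefault(g.label(i), []).append(i)
    for j in range(1, len(h) + 1):
        by_label_h.setdefault(h.label(j), []).append(j)
    if set(by_label_g) != set(by_label_h) or any(
        len(by_label_g[lab]) != len(by_label_h[lab]) for lab in by_label_g
    ):
        raise NoMappingError("gene-id multisets differ; no total mapping exists")

    total = 1
    for lab in by_label_g:
        k = len(by_label_g[lab])
        for t in range(2, k + 1):
            total *= t
        if total > MAPPING_GUARD:
            raise TooManyMappingsError(
                f"more than {MAPPING_GUARD} gene mappings; refusing"
            )

    labels = sorted(by_label_g)
    per_label_perms = [
        [
            list(zip(by_label_g[lab], perm))
            for perm in itertools.permutations(by_label_h[lab])
        ]
        for lab in labels
    ]
    for combo in itertools.product(*per_label_perms):
        mapping: dict[int, int] = {}
        for pairs in combo:
            mapping.update(pairs)
        yield mapping


def num_breakpoints(g: SignedString, h: SignedString, mapping: dict[int, int]) -> int:
    """Count the adjacencies of ``g`` that ``mapping`` does not preserve."""
    count = 0
    for i in range(1, len(g)):
        j, k = mapping[i], mapping[i + 1]
        if k != j + 1 and k != j - 1:
            count += 1
    return count


def breakpoint_distance(g: SignedString, h: SignedString) -> int:
    """Minimum unsigned break-point count over all gene mappings."""
    return min(num_breakpoints(g, h, m) for m in enumerate_gene_mappings(g, h))


def signed_pair_preserved(
    order_preserved: bool,
    first_signs_equal_ok: bool,
    second_signs_equal_ok: bool,
    first_signs_negated_ok: bool,
    second_signs_negated_ok: bool,
) -> bool:
    """Whether an adjacency survives, given order relation and sign checks.

    An adjacency (u, v) of the first string mapped to consecutive positions
    of the second survives iff the order is preserved with both signs kept,
    or the order is reversed with both signs negated.
    """
    if order_preserved:
        return first_signs_equal_ok and second_signs_equal_ok
    return first_signs_negated_ok and second_signs_negated_ok


def _sets(sign) -> frozenset[int]:
    if isinstance(sign, frozenset):
        return sign
    return frozenset((sign,))


def signs_compatible(a, b, negated: bool = False) -> bool:
    """Set-valued sign equality: some choice in ``a`` equals (the negation
    of) some choice in ``b``.  Scalars are treated as singleton sets."""
    sa, sb = _sets(a), _sets(b)
    if negated:
        sb = frozenset(-s for s in sb)
    return bool(sa & sb)


def num_signed_breakpoints(
    g: SignedString, h: SignedString, mapping: dict[int, int]
) -> int:
    """Count the signed adjacencies of ``g`` broken under ``mapping``."""
    count = 0
    for i in range(1, len(g)):
        j, k = mapping[i], mapping[i + 1]
        if k == j + 1:
            ok = g.sign(i) == h.sign(j) and g.sign(i + 1) == h.sign(k)
        elif k == j - 1:
            ok = g.sign(i) == -h.sign(j) and g.sign(i + 1) == -h.sign(k)
        else:
            ok = False
        if not ok:
            count += 1
    return count


def signed_breakpoint_distance(g: SignedString, h: SignedString) -> int:
    """Minimum signed break-point count over all gene mappings."""
    return min(num_signed_breakpoints(g, h, m) for m in enumerate_gene_mappings(g, h))


def count_signed_breakpoints_unique(
    orig: Sequence[tuple[object, object]],
    derived: Sequence[tuple[object, object]],
) -> int:
    """Signed break-point count between two duplicate-free keyed strings.

    ``orig`` and ``derived`` are sequences of ``(key, sign)`` where keys are
    unique and shared (the gene mapping is the identity on keys) and signs
    may be scalars or sign sets (a set acts as whichever sign avoids a
    break-point).  Counts break-points of ``orig``.
    """
    pos_derived = {key: idx for idx, (key, _) in enumerate(derived)}
    sign_derived = {key: sg for key, sg in derived}
    if len(pos_derived) != len(derived) or len(orig) != len(derived):
        raise NoMappingError("keyed strings must be duplicate-free and matched")
    count = 0
    for (key_a, sg_a), (key_b, sg_b) in zip(orig, orig[1:]):
        j, k = pos_derived[key_a], pos_derived[key_b]
        if k == j + 1:
            ok = signs_compatible(sg_a, sign_derived[key_a]) and signs_compatible(
                sg_b, sign_derived[key_b]
            )
        elif k == j - 1:
            ok = signs_compatible(
                sg_a, sign_derived[key_a], negated=True
            ) and signs_compatible(sg_b, sign_derived[key_b], negated=True)
        else:
            ok = False
        if not ok:
            count += 1
    return count
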