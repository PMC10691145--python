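"""Shared fixtures: the worked-example instance and seeded instance grids."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from pqdiverge.config import PenaltyConfig
from pqdiverge.pqtree import PQNode, PQTree, parse_tree
from pqdiverge.simulate import GeneratorParams, mutate_to_target, random_pqtree

PENALTY_VALUES = [Fraction(0), Fraction(1, 2), Fraction(1), Fraction(3, 2), Fraction(3)]


@pytest.fixture
def example_tree() -> PQTree:
    """The six-gene cluster used in the worked examples: a P-root over
    (P a (Q b c) d), e, f."""
    return parse_tree("(P (P +a (Q +b +c) +d) +e +f)")


@pytest.fixture
def example_nodes(example_tree):
    """(x, y, z) = root P-node, inner P-node, Q-node of the example."""
    x = example_tree.root
    y = next(c for c in x.children if c.kind == "P")
    z = next(c for c in y.children if c.kind == "Q")
    return x, y, z


def grid_instances(seed: int, n_cases: int, *, min_leaves=3, max_leaves=6,
                   max_budget=2, jump_choices=(True, False),
                   with_deletions=True):
    """Seeded stream of (tree, target, d_t, d_s, penalties) instances."""
    rng = random.Random(seed)
    for _ in range(n_cases):
        params = GeneratorParams(
            min_leaves=min_leaves,
            max_leaves=max_leaves,
            seed=rng.randrange(2**30),
            n_flips=rng.randrange(3),
            n_p_shuffles=rng.randrange(3),
            n_leaf_deletions=rng.randrange(max_budget + 1) if with_deletions else 0,
            n_insertions=rng.randrange(max_budget + 1) if with_deletions else 0,
        )
        inst_rng = random.Random(params.seed)
        tree = random_pqtree(params, inst_rng)
        target, _ = mutate_to_target(tree, params, inst_rng)
        d_t = rng.randrange(max_budget + 1) if with_deletions else 0
        d_s = rng.randrange(max_budget + 1) if with_deletions else 0
        penalties = PenaltyConfig(
            delta_q_ord=rng.choice(PENALTY_VALUES),
            delta_q_flip=rng.choice(PENALTY_VALUES),
            rho_t_del=rng.choice(PENALTY_VALUES),
            rho_s_del=rng.choice(PENALTY_VALUES),
            jump_enabled=rng.choice(jump_choices),
        )
        yield tree, target, d_t, d_s, penalties


def reorder_copy(node: PQNode, permutations: dict[int, list[int]],
                 negate_leaves: set[int]) -> PQNode:
    """Build a derived copy of ``node``: children of color c are reordered
    by ``permutations[c]`` and leaves in ``negate_leaves`` change sign.
    Colors are preserved."""
    cp = node.copy()
    for v in cp.iter_preorder():
        if v.is_leaf():
            if v.color in negate_leaves:
                v.leaf_sign = -v.leaf_sign
        elif v.color in permutations:
            v.children = [v.children[k] for k in permutations[v.color]]
    return cp
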