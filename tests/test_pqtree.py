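"""Tree model: parsing, frontiers, signs, flips."""

import random
from fractions import Fraction

import pytest

from pqdiverge.pqtree import (
    MINUS,
    PLUS,
    TreeFormatError,
    convert_two_child_q_to_p,
    flip_correction,
    frontier,
    is_flipped,
    node_sign,
    parse_signed_string,
    parse_tree,
    serialize_tree,
    tree_from_json,
    tree_to_json,
)
from pqdiverge.simulate import GeneratorParams, random_pqtree

from conftest import reorder_copy


class TestParsing:
    def test_simple_p_node(self):
        t = parse_tree("(P +a +b)")
        assert t.root.kind == "P"
        assert str(frontier(t)) == "+a +b"

    def test_example_tree_stats(self, example_tree):
        assert example_tree.m == 6
        assert example_tree.m_p == 2
        assert example_tree.m_q == 1
        assert str(frontier(example_tree)) == "+a +b +c +d +e +f"

    @pytest.mark.parametrize(
        "text",
        ["(Q +a)", "", "(P +a", "(P +a +b))", "(X +a +b)", "(P + +b)"],
    )
    def test_malformed_input(self, text):
        with pytest.raises(TreeFormatError):
            parse_tree(text)

    def test_sign_default_positive(self):
        t = parse_tree("(P a -b)")
        assert frontier(t).tokens == (("a", PLUS), ("b", MINUS))

    def test_single_leaf_tree(self):
        t = parse_tree("-g")
        assert str(frontier(t)) == "-g"

    def test_colors_preorder_and_unique(self, example_tree):
        colors = [v.color for v in example_tree.root.iter_preorder()]
        assert colors == list(range(len(colors)))

    def test_roundtrip_seeded_trees(self):
        rng = random.Random(11)
        for _ in range(50):
            params = GeneratorParams(min_leaves=2, max_leaves=9,
                                     seed=rng.randrange(2**30))
            t = random_pqtree(params)
            again = parse_tree(serialize_tree(t))
            assert serialize_tree(again) == serialize_tree(t)
            assert [v.color for v in again.root.iter_preorder()] == [
                v.color for v in t.root.iter_preorder()
            ]
            assert tree_from_json(tree_to_json(t)).m == t.m

    def test_span_additivity(self, example_tree):
        for v in example_tree.root.iter_preorder():
            if not v.is_leaf():
                assert v.span == sum(c.span for c in v.children)
        assert example_tree.root.span == len(frontier(example_tree))


class TestSignsAndFlips:
    def test_node_sign_majorities(self):
        t = parse_tree("(P +a -b (Q -c -d +e))")
        leaf_a = t.root.children[0]
        q = t.root.children[2]
        assert node_sign(leaf_a) == frozenset({PLUS})
        assert node_sign(q) == frozenset({MINUS})
        assert node_sign(t.root) == frozenset({MINUS})  # 2 plus vs 3 minus
        t2 = parse_tree("(P +a -b)")
        assert node_sign(t2.root) == frozenset({PLUS, MINUS})  # exact tie

    def test_is_flipped_leaf(self):
        t = parse_tree("(Q +a +b)")
        flipped = reorder_copy(t.root, {}, {t.root.children[0].color})
        assert is_flipped(t.root.children[0], flipped.children[0]) == 1
        assert is_flipped(t.root.children[1], flipped.children[1]) == 0

    def test_is_flipped_q_node(self, example_tree):
        _, _, z = (
            example_tree.root,
            example_tree.root.children[0],
            example_tree.root.children[0].children[1],
        )
        leaves = {v.color for v in z.leaves()}
        z_rev = reorder_copy(z, {z.color: [1, 0]}, leaves)
        assert is_flipped(z, z_rev) == 1
        z_same = reorder_copy(z, {}, set())
        assert is_flipped(z, z_same) == 0

    def test_is_flipped_identity_and_mirror(self):
        rng = random.Random(5)
        for _ in range(20):
            t = random_pqtree(GeneratorParams(min_leaves=2, max_leaves=6,
                                              seed=rng.randrange(2**30)))
            assert is_flipped(t.root, t.root.copy()) == 0
            mirror = t.root.copy()
            for v in mirror.iter_preorder():
                if v.is_leaf():
                    v.leaf_sign = -v.leaf_sign
                else:
                    v.children.reverse()
            if t.root.is_leaf():
                assert is_flipped(t.root, mirror) == 1
            else:
                assert is_flipped(t.root, mirror) == 1

    def test_is_flipped_color_mismatch(self):
        t = parse_tree("(P +a +b)")
        with pytest.raises(ValueError):
            is_flipped(t.root.children[0], t.root.children[1])

    def test_flip_correction_both_children_flipped(self, example_nodes):
        _, _, z = example_nodes
        leaves = {v.color for v in z.leaves()}
        z_rev = reorder_copy(z, {z.color: [1, 0]}, leaves)
        assert flip_correction(z, z_rev, Fraction(3)) == 6

    def test_flip_correction_zero_with_unflipped_child(self, example_nodes):
        _, _, z = example_nodes
        z_half = reorder_copy(z, {z.color: [1, 0]}, {z.children[0].color})
        assert flip_correction(z, z_half, Fraction(3)) == 0

    def test_flip_correction_excludes_p_children(self):
        # Q-node over (leaf, P-node, Q-node), everything flipped: only the
        # leaf and the Q child are refunded.
        t = parse_tree("(Q +a (P +b +c) (Q +d +e))")
        x = t.root
        perms = {v.color: list(range(len(v.children) - 1, -1, -1))
                 for v in x.iter_preorder() if not v.is_leaf()}
        negate = {v.color for v in x.leaves()}
        x_rev = reorder_copy(x, perms, negate)
        assert flip_correction(x, x_rev, Fraction(1)) == 2


class TestPreprocessing:
    def test_two_child_q_to_p(self):
        t = parse_tree("(Q (Q +a +b) (Q +c (P +d +e)))")
        out = convert_two_child_q_to_p(t)
        kinds = [v.kind for v in out.root.iter_preorder() if not v.is_leaf()]
        # root and the right child have internal children -> converted;
        # the left (Q +a +b) has height 1 -> kept
        assert out.root.kind == "P"
        assert kinds.count("Q") == 1
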