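"""General engine: deletions, budgets, cross-engine and oracle equality."""

from fractions import Fraction

import pytest

from pqdiverge.config import PenaltyConfig
from pqdiverge.cttsd import cttsd_diverge
from pqdiverge.oracle import brute_force_diverge
from pqdiverge.pqtree import frontier, parse_signed_string, parse_tree, pos_consistent
from pqdiverge.ttsd import (
    bp_delta,
    bp_delta2,
    end_fn,
    jump_violation_delta,
    length_fn,
    ttsd_diverge,
)

from conftest import grid_instances


class TestFormulas:
    def test_length_and_end(self):
        t = parse_tree("(P +a +b +c +d)")
        x = t.root
        assert length_fn(x, 1, 2) == 5
        assert end_fn(x, 3, 0, 0) == 6
        leaf = x.children[0]
        assert length_fn(leaf, 1, 0) == 0
        with pytest.raises(ValueError):
            length_fn(leaf, 2, 0)

    def test_pos_consistency(self):
        assert pos_consistent(2, +1, 4)
        assert pos_consistent(2, -1, 4)   # boundary tie: both signs
        assert not pos_consistent(0, +1, 4)
        assert pos_consistent(1, -1, 4, k_t=2)

    def test_bp_deltas(self):
        t = parse_tree("(P +a +b +c)")
        x = t.root
        a, b, c = x.children
        # adjacent, order and signs preserved
        assert bp_delta(x, a, b, neg_colors=set()) == 0
        # non-adjacent pair always a break-point under bp_delta
        assert bp_delta(x, a, c, neg_colors=set()) == 1
        # ... but not under bp_delta2 once the middle child is deleted
        assert bp_delta2(x, a, c, neg_colors=set()) == 0
        # sign negation without order reversal breaks the adjacency
        assert bp_delta(x, a, b, neg_colors={a.color}) == 1

    def test_jump_violation_delta(self):
        t = parse_tree("(P (Q +a +b +c) +d)")
        block, leaf = t.root.children
        assert jump_violation_delta({block.color}, block) == 1
        assert jump_violation_delta(set(), block) == 0
        assert jump_violation_delta({leaf.color}, leaf) == 0


class TestDeletions:
    def test_identity_zero(self, example_tree):
        pen = PenaltyConfig()
        assert ttsd_diverge(example_tree, frontier(example_tree), 0, 0, pen).score == 0

    def test_leaf_deletion_example(self):
        t = parse_tree("(P +a +b +c)")
        pen = PenaltyConfig(delta_q_ord=0, delta_q_flip=0,
                            rho_t_del=1, rho_s_del=0)
        r = ttsd_diverge(t, parse_signed_string("+a +c"), 1, 0, pen)
        assert r.score == 1
        assert r.del_t == 1 and r.del_s == 0

    def test_string_deletion_example(self):
        t = parse_tree("(Q +a +b)")
        pen = PenaltyConfig(rho_s_del=Fraction(1, 2))
        r = ttsd_diverge(t, parse_signed_string("+a +x +b"), 0, 1, pen)
        assert r.score == Fraction(1, 2)
        assert r.del_s == 1

    def test_window_flanks_are_free(self):
        # the derived window may sit anywhere in a longer target
        t = parse_tree("(Q +a +b)")
        r = ttsd_diverge(t, parse_signed_string("+u +a +b +v"), 0, 0,
                         PenaltyConfig())
        assert r.score == 0
        assert (r.start, r.end) == (2, 3)

    def test_infeasible_without_budget(self):
        t = parse_tree("(P +a +b +c)")
        r = ttsd_diverge(t, parse_signed_string("+a +c"), 0, 0, PenaltyConfig())
        assert not r.feasible

    def test_negative_budget_rejected(self, example_tree):
        with pytest.raises(ValueError):
            ttsd_diverge(example_tree, frontier(example_tree), -1, 0,
                         PenaltyConfig())

    def test_duplicate_labels_in_target(self):
        # the second 'a' starts the better window; the first is outside it
        t = parse_tree("(Q +a +b)")
        r = ttsd_diverge(t, parse_signed_string("+a +a +b"), 0, 1,
                         PenaltyConfig(rho_s_del=Fraction(1)))
        assert r.score == 0
        assert (r.start, r.end) == (2, 3)

    def test_middle_child_deletion_joins_outer_q_children(self):
        # deleting b inside (Q a b c) makes (a, c) adjacent: no order
        # penalty remains
        t = parse_tree("(Q +a +b +c)")
        pen = PenaltyConfig(delta_q_ord=3, delta_q_flip=0, rho_t_del=1,
                            rho_s_del=1)
        r = ttsd_diverge(t, parse_signed_string("+a +c"), 1, 0, pen)
        assert r.score == 1  # just the deletion
        oracle = brute_force_diverge(t, parse_signed_string("+a +c"), 1, 0, pen)
        assert oracle.score == 1


class TestEquivalences:
    def test_matches_cttsd_on_permutations(self):
        for tree, target, _, _, pen in grid_instances(
            2024, 60, max_leaves=7, with_deletions=False
        ):
            a = cttsd_diverge(tree, target, pen)
            b = ttsd_diverge(tree, target, 0, 0, pen)
            assert (a.feasible, a.score) == (b.feasible, b.score)

    def test_matches_oracle_with_deletions(self):
        for tree, target, d_t, d_s, pen in grid_instances(4096, 80):
            got = ttsd_diverge(tree, target, d_t, d_s, pen)
            want = brute_force_diverge(tree, target, d_t, d_s, pen)
            assert (got.feasible, got.score) == (want.feasible, want.score), (
                f"tree={frontier(tree)} target={target} "
                f"d_t={d_t} d_s={d_s} pen={pen}"
            )

    def test_budget_monotonicity(self):
        for tree, target, _, _, pen in grid_instances(515, 25):
            prev = None
            for d in range(3):
                r = ttsd_diverge(tree, target, d, d, pen)
                if prev is not None and prev.feasible:
                    assert r.feasible
                    assert r.score <= prev.score
                prev = r

    def test_budget_accounting(self):
        for tree, target, d_t, d_s, pen in grid_instances(77, 30):
            r = ttsd_diverge(tree, target, d_t, d_s, pen)
            if not r.feasible:
                continue
            assert r.del_t <= d_t and r.del_s <= d_s
            assert r.score >= pen.rho_t_del * r.del_t + pen.rho_s_del * r.del_s
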