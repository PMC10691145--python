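"""Constrained engine: worked-example trace, infeasibility, properties."""

import random
from fractions import Fraction

import pytest

from pqdiverge.config import PenaltyConfig
from pqdiverge.cttsd import cttsd_diverge
from pqdiverge.oracle import brute_force_diverge
from pqdiverge.pqtree import frontier, parse_signed_string, parse_tree
from pqdiverge.simulate import GeneratorParams, mutate_to_target, random_pqtree

from conftest import PENALTY_VALUES

PEN33 = PenaltyConfig(delta_q_ord=Fraction(3), delta_q_flip=Fraction(3))


class TestWorkedExample:
    """Tree (P (P +a (Q +b +c) +d) +e +f) against +f -c -b -a -d -e with
    delta_q_ord = delta_q_flip = 3."""

    @pytest.fixture
    def run(self, example_tree):
        target = parse_signed_string("+f -c -b -a -d -e")
        return cttsd_diverge(example_tree, target, PEN33, trace=True)

    def test_q_node_entry(self, run, example_nodes):
        _, _, z = example_nodes
        tr = run.node_trace[z.color]
        assert (tr["start"], tr["end"]) == (2, 3)
        assert tr["score"] == 3
        assert tr["children_dist"] == 6
        assert tr["flip_correction"] == 6
        assert tr["d_sbp"] == 0

    def test_inner_p_node_entry(self, run, example_nodes):
        _, y, _ = example_nodes
        tr = run.node_trace[y.color]
        assert (tr["start"], tr["end"]) == (2, 5)
        assert tr["score"] == 10
        assert tr["d_sbp"] == 1
        assert tr["jump"] == 0

    def test_root_break_point_term(self, run, example_nodes):
        x, _, _ = example_nodes
        assert run.node_trace[x.color]["d_sbp"] == 2
        assert run.node_trace[x.color]["jump"] == 0

    def test_total_matches_brute_force(self, run, example_tree):
        target = parse_signed_string("+f -c -b -a -d -e")
        oracle = brute_force_diverge(example_tree, target, 0, 0, PEN33)
        assert run.score == oracle.score

    def test_definition_level_instance_matches_oracle(self, example_tree):
        # same tree, +e instead of -e, flip penalty zero
        target = parse_signed_string("+f -c -b -a -d +e")
        pen = PenaltyConfig(delta_q_ord=Fraction(3), delta_q_flip=Fraction(0))
        got = cttsd_diverge(example_tree, target, pen)
        oracle = brute_force_diverge(example_tree, target, 0, 0, pen)
        assert got.score == oracle.score


class TestFeasibility:
    def test_identity_is_zero(self, example_tree):
        assert cttsd_diverge(example_tree, frontier(example_tree), PEN33).score == 0

    def test_underivable_target(self):
        t = parse_tree("(Q +a +b +c)")
        r = cttsd_diverge(t, parse_signed_string("+b +a +c"), PEN33)
        assert not r.feasible
        assert r.render_score() == "NO"

    def test_q_node_reversal_derivable(self):
        t = parse_tree("(Q +a +b +c)")
        r = cttsd_diverge(t, parse_signed_string("-c -b -a"), PEN33)
        assert r.feasible

    @pytest.mark.parametrize(
        "target", ["+a +b", "+a +b +x", "+a +a +b"],
    )
    def test_input_validation(self, target):
        t = parse_tree("(P +a +b +c)")
        with pytest.raises(ValueError):
            cttsd_diverge(t, parse_signed_string(target), PEN33)


class TestProperties:
    def test_identity_zero_across_penalties(self):
        rng = random.Random(7)
        for _ in range(40):
            t = random_pqtree(GeneratorParams(min_leaves=2, max_leaves=7,
                                              seed=rng.randrange(2**30)))
            pen = PenaltyConfig(
                delta_q_ord=rng.choice(PENALTY_VALUES),
                delta_q_flip=rng.choice(PENALTY_VALUES),
                jump_enabled=rng.random() < 0.5,
            )
            assert cttsd_diverge(t, frontier(t), pen).score == 0

    def test_non_negative_and_monotone_in_penalties(self):
        rng = random.Random(13)
        for _ in range(40):
            params = GeneratorParams(min_leaves=3, max_leaves=6,
                                     seed=rng.randrange(2**30),
                                     n_flips=rng.randrange(3),
                                     n_p_shuffles=rng.randrange(3))
            inst = random.Random(params.seed)
            t = random_pqtree(params, inst)
            target, _ = mutate_to_target(t, params, inst)
            lo = PenaltyConfig(delta_q_ord=Fraction(1, 2),
                               delta_q_flip=Fraction(1, 2))
            hi_ord = PenaltyConfig(delta_q_ord=Fraction(2),
                                   delta_q_flip=Fraction(1, 2))
            hi_flip = PenaltyConfig(delta_q_ord=Fraction(1, 2),
                                    delta_q_flip=Fraction(2))
            r_lo = cttsd_diverge(t, target, lo)
            assert r_lo.feasible and r_lo.score >= 0
            assert cttsd_diverge(t, target, hi_ord).score >= r_lo.score
            assert cttsd_diverge(t, target, hi_flip).score >= r_lo.score

    def test_matches_oracle_on_small_instances(self):
        rng = random.Random(31)
        for _ in range(60):
            params = GeneratorParams(min_leaves=2, max_leaves=6,
                                     seed=rng.randrange(2**30),
                                     n_flips=rng.randrange(3),
                                     n_p_shuffles=rng.randrange(3))
            inst = random.Random(params.seed)
            t = random_pqtree(params, inst)
            target, _ = mutate_to_target(t, params, inst)
            pen = PenaltyConfig(
                delta_q_ord=rng.choice(PENALTY_VALUES),
                delta_q_flip=rng.choice(PENALTY_VALUES),
                jump_enabled=rng.random() < 0.7,
            )
            got = cttsd_diverge(t, target, pen)
            want = brute_force_diverge(t, target, 0, 0, pen)
            assert (got.feasible, got.score) == (want.feasible, want.score)
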