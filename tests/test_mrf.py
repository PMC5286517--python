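"""MRF energy model, clamping, and exact sum-product marginals."""

import math

import numpy as np
import pytest

from grace_grn import mrf
from grace_grn.datatypes import Hyperparameters

from conftest import enumerate_marginals, make_module, random_tree_module


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestEnergy:
    def test_singleton_at_threshold_is_symmetric(self):
        m = make_module({"g": 0.5})
        theta = Hyperparameters(0.5, 1.0)
        assert mrf.energy(m, {("R", "g"): 0}, theta) == pytest.approx(0.0)
        assert mrf.energy(m, {("R", "g"): 1}, theta) == pytest.approx(0.0)

    def test_zero_coupling_separates(self):
        m = make_module({"a": 0.7, "b": 0.3}, [("a", "b", 0.0)])
        theta = Hyperparameters(0.5, 2.0)
        for xa in (0, 1):
            for xb in (0, 1):
                e = mrf.energy(m, {("R", "a"): xa, ("R", "b"): xb}, theta)
                ea = -(0.7 - 0.5) * (2 * xa - 1)
                eb = -(0.3 - 0.5) * (2 * xb - 1)
                assert e == pytest.approx(ea + eb)

    def test_hand_evaluated_pair(self):
        # (v - gamma) = (+0.2, -0.1), lambda = 1, coupling 0.5, state (1, 1)
        m = make_module({"a": 0.7, "b": 0.4}, [("a", "b", 0.5)])
        theta = Hyperparameters(0.5, 1.0)
        e = mrf.energy(m, {("R", "a"): 1, ("R", "b"): 1}, theta)
        assert e == pytest.approx(-0.2 + 0.1 - 0.5)

    def test_unassigned_node_errors(self):
        m = make_module({"a": 0.7, "b": 0.4}, [("a", "b", 0.5)])
        with pytest.raises(ValueError, match="missing"):
            mrf.energy(m, {("R", "a"): 1}, Hyperparameters(0.5, 1.0))


class TestJointProbability:
    def test_singleton_at_threshold_is_uniform(self):
        m = make_module({"g": 0.5})
        theta = Hyperparameters(0.5, 1.0)
        assert mrf.joint_probability(m, {("R", "g"): 0}, theta) == pytest.approx(0.5)
        assert mrf.joint_probability(m, {("R", "g"): 1}, theta) == pytest.approx(0.5)

    def test_normalization_over_all_states(self):
        m = make_module({"a": 0.9, "b": 0.2, "c": 0.5},
                        [("a", "b", 0.6), ("b", "c", 0.3)])
        theta = Hyperparameters(0.4, 1.3)
        # a is clamped (0.9 > 0.4): sum over free configurations only
        total = 0.0
        for xb in (0, 1):
            for xc in (0, 1):
                total += mrf.joint_probability(
                    m, {("R", "a"): 1, ("R", "b"): xb, ("R", "c"): xc}, theta
                )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_clamp_violating_state_has_zero_probability(self):
        m = make_module({"a": 0.9, "b": 0.2}, [("a", "b", 0.5)])
        theta = Hyperparameters(0.4, 1.0)
        assert mrf.joint_probability(m, {("R", "a"): 0, ("R", "b"): 1}, theta) == 0.0

    def test_chain_matches_enumeration(self, rng):
        m = make_module(
            {"a": 0.8, "b": 0.35, "c": 0.6}, [("a", "b", 0.7), ("b", "c", 0.2)]
        )
        theta = Hyperparameters(0.9, 0.8)  # nothing clamped
        probs = {}
        z = 0.0
        for bits in np.ndindex(2, 2, 2):
            x = dict(zip(m.nodes, (int(v) for v in bits)))
            w = math.exp(-mrf.energy(m, x, theta))
            probs[bits] = w
            z += w
        for bits, w in probs.items():
            x = dict(zip(m.nodes, (int(v) for v in bits)))
            assert mrf.joint_probability(m, x, theta) == pytest.approx(w / z, abs=1e-12)


class TestClamping:
    def test_weight_equal_to_gamma_is_not_clamped(self):
        m = make_module({"g": 0.5})
        assert mrf.clamp_high_confidence(m, Hyperparameters(0.5, 1.0)) == set()

    def test_all_above_gamma_gives_unit_marginals(self):
        m = make_module({"a": 0.8, "b": 0.9}, [("a", "b", 0.4)])
        marg = mrf.belief_propagation(m, Hyperparameters(0.5, 1.0))
        assert all(p == 1.0 for p in marg.values())

    def test_conditional_marginals_match_enumeration(self):
        # chain low - high - low: middle clamped, flanks conditioned on it
        m = make_module({"l1": 0.3, "h": 0.9, "l2": 0.25},
                        [("l1", "h", 0.8), ("h", "l2", 0.6)])
        theta = Hyperparameters(0.5, 1.2)
        assert mrf.clamp_high_confidence(m, theta) == {("R", "h")}
        marg = mrf.belief_propagation(m, theta)
        oracle = enumerate_marginals(m, theta)
        for node in m.nodes:
            assert marg[node] == pytest.approx(oracle[node], abs=1e-12)


class TestBeliefPropagation:
    def test_singleton_closed_form(self):
        m = make_module({"g": 0.75})
        # unconditioned two-state marginal; with clamping this link pins to 1
        marg = mrf.belief_propagation(m, Hyperparameters(0.25, 1.0), clamp=False)
        assert marg[("R", "g")] == pytest.approx(sigmoid(2 * 0.5), abs=1e-12)
        assert marg[("R", "g")] == pytest.approx(0.73106, abs=1e-5)
        assert mrf.belief_propagation(m, Hyperparameters(0.25, 1.0))[("R", "g")] == 1.0

    def test_random_trees_match_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 13))
            m = random_tree_module(rng, n)
            theta = Hyperparameters(float(rng.uniform(0, 1)), float(rng.uniform(0.01, 2.5)))
            marg = mrf.belief_propagation(m, theta)
            oracle = enumerate_marginals(m, theta)
            for node in m.nodes:
                assert marg[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_cycle_rejected(self):
        # 3 nodes, 2 edges that don't span -> duplicated pair leaves a node detached
        m = make_module({"a": 0.5, "b": 0.5, "c": 0.5},
                        [("a", "b", 0.5), ("a", "b", 0.6)])
        with pytest.raises(ValueError, match="spanning tree"):
            mrf.belief_propagation(m, Hyperparameters(0.9, 1.0))


class TestPrune:
    def test_marginal_exactly_half_is_removed(self):
        m = make_module({"g": 0.5})
        assert mrf.prune(m, Hyperparameters(0.5, 1.0)) == set()

    def test_isolated_link_below_gamma_removed(self):
        m = make_module({"g": 0.4})
        assert mrf.prune(m, Hyperparameters(0.5, 1.0)) == set()

    def test_weak_link_rescued_by_clamped_neighbor(self):
        m = make_module({"weak": 0.45, "strong": 0.9}, [("weak", "strong", 0.8)])
        theta = Hyperparameters(0.5, 1.0)
        retained = mrf.prune(m, theta)
        assert ("R", "weak") in retained and ("R", "strong") in retained
        # sanity: the same weak link alone would be removed
        alone = make_module({"weak": 0.45})
        assert mrf.prune(alone, theta) == set()

    def test_rescue_requires_sufficient_coupling(self):
        weak = {"weak": 0.40}
        theta = Hyperparameters(0.5, 1.0)
        # lam*coupling = 0.05 < gamma - v = 0.10: rescue falls short
        m_short = make_module({**weak, "strong": 0.9}, [("weak", "strong", 0.05)])
        assert ("R", "weak") not in mrf.prune(m_short, theta)
        m_ok = make_module({**weak, "strong": 0.9}, [("weak", "strong", 0.2)])
        assert ("R", "weak") in mrf.prune(m_ok, theta)


class TestLimits:
    def test_marginal_nondecreasing_in_lambda(self):
        m = make_module({"weak": 0.4, "strong": 0.9}, [("weak", "strong", 0.5)])
        previous = -1.0
        for lam in np.linspace(0.001, 2.5, 15):
            p = mrf.belief_propagation(m, Hyperparameters(0.5, float(lam)))[("R", "weak")]
            assert p >= previous - 1e-12
            previous = p

    def test_retained_set_shrinks_as_gamma_rises(self, rng):
        m = random_tree_module(rng, 8)
        lam = 1e-9  # decoupled limit: pure thresholding
        sizes = [len(mrf.prune(m, Hyperparameters(g, lam)))
                 for g in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)

    def test_small_lambda_limit_equals_singleton_form(self, rng):
        m = random_tree_module(rng, 6)
        theta = Hyperparameters(0.5, 1e-12)
        marg = mrf.belief_propagation(m, theta)
        for node in m.nodes:
            v = m.weights[node]
            if v > 0.5:
                assert marg[node] == 1.0
            else:
                assert marg[node] == pytest.approx(sigmoid(2 * (v - 0.5)), abs=1e-9)
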