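"""Coarse-to-fine hyperparameter learning."""

import numpy as np
import pytest

from grace_grn import hyperopt, meta_network, mrf, synthetic
from grace_grn.datatypes import (
    CoFunctionNetwork,
    GeneRegulatoryNetwork,
    GoldStandards,
    Hyperparameters,
)


@pytest.fixture(scope="module")
def small_benchmark():
    wb = synthetic.generate_weighted_grn(
        synthetic.WeightedGrnParams(n_tfs=6, n_genes=80, mean_targets_per_tf=6.0),
        seed=11,
    )
    modules = meta_network.build_modules(wb.grn, wb.cofn)
    return wb, modules


class TestEvaluateTheta:
    def test_gamma_below_all_weights_retains_everything(self, small_benchmark):
        wb, modules = small_benchmark
        low = min(wb.grn.links.values()) - 0.01
        p, r, f = hyperopt.evaluate_theta(
            Hyperparameters(max(low, 0.0), 1.0), modules, wb.gold, wb.grn
        )
        assert r == 1.0  # identity pruning keeps all supported co-regulation
        retained = mrf.prune_network(modules, Hyperparameters(max(low, 0.0), 1.0))
        assert retained == set(wb.grn.links)

    def test_gamma_above_all_weights_empties_network(self, small_benchmark):
        wb, modules = small_benchmark
        p, r, f = hyperopt.evaluate_theta(
            Hyperparameters(1.0, 1e-6), modules, wb.gold, wb.grn
        )
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_hand_checked_toy_scores(self):
        # two singleton modules: one above gamma (kept), one below (removed)
        grn = GeneRegulatoryNetwork({("A", "g1"): 0.9, ("B", "g2"): 0.2})
        modules = meta_network.build_modules(grn, CoFunctionNetwork())
        gold = GoldStandards.build([("A", "g1"), ("B", "g2")], [])
        p, r, f = hyperopt.evaluate_theta(
            Hyperparameters(0.5, 1.0), modules, gold, grn
        )
        assert p == 1.0  # the single retained link is gold
        # no co-annotation gold -> recall degenerates to 0
        assert r == 0.0


class TestGridSearch:
    def test_resolution_two_gives_four_evaluations(self, small_benchmark):
        wb, modules = small_benchmark
        space = hyperopt.SearchSpace.from_modules(modules)
        res = hyperopt.grid_search(modules, wb.gold, wb.grn, space, (2, 2))
        assert len(res.trace) == 4

    def test_constant_objective_ties_to_lowest_corner(self, small_benchmark):
        _, modules = small_benchmark
        grn = GeneRegulatoryNetwork(
            {n: w for m in modules for n, w in m.weights.items()}
        )
        # empty-ish gold: f is 0 everywhere -> tie rule picks lowest lambda, gamma
        gold = GoldStandards.build([("ZZZ", "none")], [("x1", "x2")])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hyperopt.grid_search(
                modules, gold, grn, hyperopt.SearchSpace.from_modules(modules), (4, 4)
            )
        weights = [w for m in modules for w in m.weights.values()]
        assert res.theta.lam == pytest.approx(0.001)
        assert res.theta.gamma == pytest.approx(min(weights))

    def test_sub_space_brackets_best_cell(self, small_benchmark):
        wb, modules = small_benchmark
        space = hyperopt.SearchSpace.from_modules(modules)
        res = hyperopt.grid_search(modules, wb.gold, wb.grn, space, (6, 6))
        assert res.sub_space.contains(res.theta)
        assert space.gamma_range[0] <= res.sub_space.gamma_range[0]
        assert res.sub_space.gamma_range[1] <= space.gamma_range[1]


class TestSimulatedAnnealing:
    SPACE = hyperopt.SearchSpace((0.0, 1.0), (0.001, 2.5))

    def test_constant_objective_returns_lowest_lambda_visited(self):
        score = lambda theta: (0.5, 0.5, 0.5)
        theta, trace = hyperopt.simulated_annealing(
            score, self.SPACE, Hyperparameters(0.5, 1.0),
            hyperopt.AnnealingConfig(n_levels=10, proposals_per_level=3), seed=1,
        )
        visited_lams = [row[1] for row in trace]
        assert theta.lam == min(visited_lams)

    def test_finds_sharp_optimum(self):
        target = Hyperparameters(0.31, 0.9)

        def score(theta):
            f = np.exp(-20 * (theta.gamma - target.gamma) ** 2
                       - 5 * (theta.lam - target.lam) ** 2)
            return 0.0, 0.0, float(f)

        hits = 0
        for seed in range(5):
            theta, _ = hyperopt.simulated_annealing(
                score, self.SPACE, Hyperparameters(0.9, 2.0),
                hyperopt.AnnealingConfig(n_levels=60, proposals_per_level=4), seed=seed,
            )
            if abs(theta.gamma - target.gamma) < 0.15 and abs(theta.lam - target.lam) < 0.4:
                hits += 1
        assert hits >= 4

    def test_two_equal_optima_resolve_to_lowest_lambda(self):
        # two flat optima around lam 0.1 and lam 2.0; the walk visits both
        def score(theta):
            f = 1.0 if (abs(theta.lam - 0.1) < 0.1 or abs(theta.lam - 2.0) < 0.1) else 0.8
            return 0.0, 0.0, f

        theta, trace = hyperopt.simulated_annealing(
            score, self.SPACE, Hyperparameters(0.5, 2.0),
            hyperopt.AnnealingConfig(n_levels=80, proposals_per_level=4), seed=3,
        )
        assert any(abs(row[1] - 0.1) < 0.1 for row in trace)  # low optimum visited
        assert abs(theta.lam - 0.1) < 0.1

    def test_zero_iterations_returns_init(self):
        theta, _ = hyperopt.simulated_annealing(
            lambda t: (0, 0, 0.2), self.SPACE, Hyperparameters(0.4, 0.4),
            hyperopt.AnnealingConfig(n_levels=0), seed=0,
        )
        assert theta == Hyperparameters(0.4, 0.4)

    def test_init_outside_subspace_rejected(self):
        with pytest.raises(ValueError, match="sub-space"):
            hyperopt.simulated_annealing(
                lambda t: (0, 0, 0), self.SPACE, Hyperparameters(2.0, 1.0),
            )


class TestLearnTheta:
    def test_never_worse_than_grid_beyond_tolerance(self, small_benchmark):
        wb, modules = small_benchmark
        cfg = hyperopt.AnnealingConfig(n_levels=10, proposals_per_level=2)
        res = hyperopt.learn_theta(
            modules, wb.gold, wb.grn, grid_resolution=(5, 5), annealing=cfg, seed=2
        )
        trace_f = {(g, l): f for g, l, _, _, f in res.trace}
        grid_f = trace_f[(res.grid_best.gamma, res.grid_best.lam)]
        _, _, final_f = hyperopt.evaluate_theta(
            res.theta, modules, wb.gold, wb.grn, p_max=res.p_max
        )
        assert final_f >= grid_f - cfg.delta_f * max(grid_f, final_f) - 1e-12

    def test_bitwise_reproducible(self, small_benchmark):
        wb, modules = small_benchmark
        kwargs = dict(grid_resolution=(4, 4),
                      annealing=hyperopt.AnnealingConfig(n_levels=6, proposals_per_level=2),
                      seed=9)
        a = hyperopt.learn_theta(modules, wb.gold, wb.grn, **kwargs)
        b = hyperopt.learn_theta(modules, wb.gold, wb.grn, **kwargs)
        assert a.theta == b.theta
        assert a.trace == b.trace
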