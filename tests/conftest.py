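"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's inference code paths:
marginals come from exhaustive state enumeration, spanning trees from
exhaustive enumeration over all trees, and the Fisher tail from a direct
hypergeometric sum.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from grace_grn.datatypes import Hyperparameters, MetaEdge, MetaModule


def make_module(weights: dict, edges: list[tuple] | None = None, module_id: int = 0,
                regulator: str = "R") -> MetaModule:
    """Build a module from {target: weight} and [(target_a, target_b, coupling)]."""
    nodes = tuple(sorted((regulator, t) for t in weights))
    w = {(regulator, t): v for t, v in weights.items()}
    tree = tuple(
        MetaEdge((regulator, a), (regulator, b), c) for a, b, c in (edges or [])
    )
    return MetaModule(module_id=module_id, regulator=regulator, nodes=nodes,
                      weights=w, tree_edges=tree)


def enumerate_marginals(module: MetaModule, theta: Hyperparameters):
    """Brute-force marginals: sum exp(-E) over all states, clamped links fixed at 1.

    Energy is recomputed here from first principles (not via grace_grn.mrf).
    """
    gamma, lam = theta
    nodes = list(module.nodes)
    clamped = [n for n in nodes if module.weights[n] > gamma]
    free = [n for n in nodes if n not in clamped]
    z = 0.0
    p1 = {n: 0.0 for n in nodes}
    for bits in itertools.product((0, 1), repeat=len(free)):
        x = {n: 1 for n in clamped}
        x.update(dict(zip(free, bits)))
        e = 0.0
        for n in nodes:
            e -= (module.weights[n] - gamma) * (2 * x[n] - 1)
        for edge in module.tree_edges:
            e -= lam * edge.weight * (2 * x[edge.link_a] - 1) * (2 * x[edge.link_b] - 1)
        w = math.exp(-e)
        z += w
        for n in nodes:
            if x[n] == 1:
                p1[n] += w
    return {n: v / z for n, v in p1.items()}


def enumerate_max_spanning_tree_weight(n_nodes: int, edges: list[tuple[int, int, float]]):
    """Maximum total weight over all spanning trees of a connected graph.

    Exhaustive: tries every (n_nodes - 1)-subset of edges and keeps the
    acyclic connected ones.  Returns -inf if the graph is disconnected.
    """
    best = -math.inf
    for subset in itertools.combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for a, b, _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[rb] = ra
        if ok:
            best = max(best, sum(w for _, _, w in subset))
    return best


def hypergeom_tail(k: int, n_draw: int, n_success: int, n_pop: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct summation."""
    total = 0.0
    for i in range(k, min(n_draw, n_success) + 1):
        total += (
            math.comb(n_success, i)
            * math.comb(n_pop - n_success, n_draw - i)
            / math.comb(n_pop, n_draw)
        )
    return total


def random_tree_module(rng: np.random.Generator, n_nodes: int) -> MetaModule:
    """A random spanning-tree module with uniform weights and couplings."""
    weights = {f"g{i}": float(rng.uniform(0.0, 1.0)) for i in range(n_nodes)}
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append((f"g{j}", f"g{i}", float(rng.uniform(0.0, 1.0))))
    return make_module(weights, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
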