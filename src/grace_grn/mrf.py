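"""Binary pairwise Markov random fields over spanning-tree modules.

Each link ``l`` of a module carries a binary state ``x_l`` (1 = keep,
0 = remove).  With spins ``s_l = 2 x_l - 1`` the module energy is

    E(x) = - sum_l (v_l - gamma) * s_l
           - lam * sum_{(l,l') in tree} v_delta(l,l') * s_l * s_l'

and ``p(x) = exp(-E(x)) / Z``.  This Ising parameterization is THE core
modeling assumption of the pruner: it favours links whose weight exceeds the
learned threshold gamma, and rewards strongly coupled link pairs (high
co-functionality, similar weights) for sharing a state.  For a single-link
module it reduces to ``p(x=1) = sigmoid(2 (v - gamma))``, i.e. removal
exactly when ``v <= gamma``.

Links with ``v > gamma`` (strictly) are clamped to ``x = 1`` — undirected
models are closed under conditioning — so a confident link can rescue weak
co-functional neighbours but can never be voted out by them.  Clamping is
implemented as evidence (a delta potential at ``x = 1``), not graph surgery,
so module topology is preserved.

Marginals are exact: two-pass sum-product message passing on the module
tree, in the log domain with per-message max-normalization.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np

from .datatypes import Hyperparameters, LinkKey, MetaModule

__all__ = [
    "energy",
    "log_partition",
    "joint_probability",
    "clamp_high_confidence",
    "belief_propagation",
    "prune",
    "prune_network",
]

_NEG_INF = -np.inf


def energy(module: MetaModule, x: Mapping[LinkKey, int], theta: Hyperparameters) -> float:
    """Module energy of a joint 0/1 state assignment."""
    unassigned = [n for n in module.nodes if n not in x]
    if unassigned:
        raise ValueError(f"state missing for nodes: {unassigned[:3]}")
    gamma, lam = theta
    e = 0.0
    for node in module.nodes:
        s = 2 * int(x[node]) - 1
        e -= (module.weights[node] - gamma) * s
    for edge in module.tree_edges:
        s_a = 2 * int(x[edge.link_a]) - 1
        s_b = 2 * int(x[edge.link_b]) - 1
        e -= lam * edge.weight * s_a * s_b
    return e


def clamp_high_confidence(module: MetaModule, theta: Hyperparameters) -> set[LinkKey]:
    """Links fixed to x=1: weight strictly above gamma."""
    return {n for n in module.nodes if module.weights[n] > theta.gamma}


def _log_potentials(module: MetaModule, theta: Hyperparameters, clamp: bool = True):
    """Per-node log potentials (shape (2,), index = state) with clamp evidence."""
    gamma, _ = theta
    clamped = clamp_high_confidence(module, theta) if clamp else set()
    phi = {}
    for node in module.nodes:
        h = module.weights[node] - gamma
        p = np.array([-h, h], dtype=float)  # log phi(x) = h * s
        if node in clamped:
            p[0] = _NEG_INF
        phi[node] = p
    return phi, clamped


def _tree_order(module: MetaModule) -> tuple[list[LinkKey], dict[LinkKey, LinkKey], dict]:
    """Root the module tree; BFS order, parent map, and adjacency with couplings."""
    adj: dict[LinkKey, list[tuple[LinkKey, float]]] = {n: [] for n in module.nodes}
    for e in module.tree_edges:
        adj[e.link_a].append((e.link_b, e.weight))
        adj[e.link_b].append((e.link_a, e.weight))
    root = module.nodes[0]
    order = [root]
    parent: dict[LinkKey, LinkKey] = {}
    seen = {root}
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for nb, _ in adj[node]:
            if nb not in seen:
                seen.add(nb)
                parent[nb] = node
                order.append(nb)
    if len(order) != len(module.nodes):
        raise ValueError(
            f"module {module.module_id}: edge set is not a spanning tree "
            f"(reached {len(order)} of {len(module.nodes)} nodes)"
        )
    return order, parent, adj


def _edge_logpsi(coupling: float, lam: float) -> np.ndarray:
    """2x2 log pairwise potential, [x_i, x_j] indexed; log psi = lam*w*s_i*s_j."""
    j = lam * coupling
    return np.array([[j, -j], [-j, j]], dtype=float)


def _logsumexp2(a: np.ndarray) -> float:
    m = np.max(a)
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + math.log(np.exp(a - m).sum()))


def log_partition(module: MetaModule, theta: Hyperparameters) -> float:
    """log Z over non-clamped configurations (clamped links fixed at 1), by tree DP."""
    phi, _ = _log_potentials(module, theta)
    order, parent, adj = _tree_order(module)
    lam = theta.lam
    # upward pass, unnormalized (log domain is stable enough at module scale)
    up: dict[LinkKey, np.ndarray] = {}
    for node in reversed(order):
        msg = phi[node].copy()
        for nb, w in adj[node]:
            if parent.get(nb) == node:
                msg = msg + up[nb]
        if node in parent:
            w = next(w for nb, w in adj[node] if nb == parent[node])
            logpsi = _edge_logpsi(w, lam)
            out = np.array([
                _logsumexp2(msg + logpsi[:, xp]) for xp in (0, 1)
            ])
            up[node] = out
        else:
            up[node] = msg  # root accumulates everything
    return _logsumexp2(up[order[0]])


def joint_probability(
    module: MetaModule, x: Mapping[LinkKey, int], theta: Hyperparameters
) -> float:
    """Probability of one joint configuration under the clamped module MRF.

    A configuration assigning 0 to a clamped link has probability 0.
    """
    clamped = clamp_high_confidence(module, theta)
    if any(int(x[n]) == 0 for n in clamped):
        return 0.0
    return math.exp(-energy(module, x, theta) - log_partition(module, theta))


def belief_propagation(
    module: MetaModule, theta: Hyperparameters, clamp: bool = True
) -> dict[LinkKey, float]:
    """Exact marginals p_l = P(x_l = 1) via two-pass sum-product on the tree.

    With ``clamp=False`` no evidence is applied and the unconditioned
    marginals are returned (for a single link this is the closed form
    ``sigmoid(2 (v - gamma))``); the retention rule ``p > 1/2`` is identical
    either way for an isolated link.
    """
    phi, clamped = _log_potentials(module, theta, clamp)
    order, parent, adj = _tree_order(module)
    lam = theta.lam

    def normalize(m: np.ndarray) -> np.ndarray:
        return m - np.max(m)

    # messages keyed by (source, destination)
    msg: dict[tuple[LinkKey, LinkKey], np.ndarray] = {}

    def compute_message(src: LinkKey, dst: LinkKey, coupling: float) -> np.ndarray:
        acc = phi[src].copy()
        for nb, _ in adj[src]:
            if nb != dst:
                acc = acc + msg[(nb, src)]
        logpsi = _edge_logpsi(coupling, lam)
        out = np.array([_logsumexp2(acc + logpsi[:, xd]) for xd in (0, 1)])
        return normalize(out)

    # leaves -> root
    for node in reversed(order):
        if node in parent:
            par = parent[node]
            w = next(w for nb, w in adj[node] if nb == par)
            msg[(node, par)] = compute_message(node, par, w)
    # root -> leaves
    for node in order:
        for nb, w in adj[node]:
            if parent.get(nb) == node:
                msg[(node, nb)] = compute_message(node, nb, w)

    marginals: dict[LinkKey, float] = {}
    for node in module.nodes:
        if node in clamped:
            marginals[node] = 1.0
            continue
        b = phi[node].copy()
        for nb, _ in adj[node]:
            b = b + msg[(nb, node)]
        b = b - _logsumexp2(b)
        marginals[node] = float(np.exp(b[1]))
    return marginals


def prune(module: MetaModule, theta: Hyperparameters) -> set[LinkKey]:
    """Retain links with marginal strictly above 1/2 (clamped links always)."""
    marginals = belief_propagation(module, theta)
    return {n for n, p in marginals.items() if p > 0.5}


def prune_network(
    modules: Iterable[MetaModule], theta: Hyperparameters
) -> set[LinkKey]:
    """Prune every module at a common theta and union the retained links."""
    retained: set[LinkKey] = set()
    for module in modules:
        retained |= prune(module, theta)
    return retained
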