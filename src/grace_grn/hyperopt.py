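"""Hyperparameter learning for theta = (gamma, lambda).

Coarse-to-fine: a grid over gamma (at empirical weight quantiles, so the
grid adapts to the weight distribution) and lambda (log-spaced over a range
spanning several decades, default [0.001, 2.5]) locates the best cell; a
simulated-annealing refinement then searches the cell's neighbourhood.
Because several near-equivalent optima typically exist, the final pick is
conservative: among all visited parameter sets scoring within a small
fraction of the best f_beta, the one with the smallest lambda (then the
smallest gamma) wins — a low coupling penalty keeps the model from
over-predicting master regulators.

Precision scaling: raw precision is divided by the maximum raw precision
seen on the grid (frozen through annealing, capped at 1), so the precision
surface reaches 1 despite sparse gold standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mrf, objective
from .datatypes import GeneRegulatoryNetwork, GoldStandards, Hyperparameters, MetaModule

__all__ = [
    "SearchSpace",
    "AnnealingConfig",
    "SearchResult",
    "evaluate_theta",
    "grid_search",
    "simulated_annealing",
    "learn_theta",
]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box for (gamma, lambda)."""

    gamma_range: tuple[float, float]
    lam_range: tuple[float, float] = (0.001, 2.5)

    def __post_init__(self):
        if self.gamma_range[0] > self.gamma_range[1] or self.lam_range[0] > self.lam_range[1]:
            raise ValueError("empty search space")
        if self.lam_range[0] <= 0:
            raise ValueError("lambda range must be positive")

    @classmethod
    def from_modules(
        cls, modules: Sequence[MetaModule], lam_range: tuple[float, float] = (0.001, 2.5)
    ) -> "SearchSpace":
        weights = _module_weights(modules)
        return cls((float(weights.min()), float(weights.max())), lam_range)

    def contains(self, theta: Hyperparameters) -> bool:
        return (
            self.gamma_range[0] <= theta.gamma <= self.gamma_range[1]
            and self.lam_range[0] <= theta.lam <= self.lam_range[1]
        )


@dataclass(frozen=True)
class AnnealingConfig:
    """Geometric-cooling Metropolis schedule (engineering defaults, all tunable)."""

    t0: float = 1.0
    alpha: float = 0.9
    n_levels: int = 50
    proposals_per_level: int = 4
    step_frac: float = 0.1  # proposal sigma as a fraction of sub-space width
    delta_f: float = 0.01   # near-optimal band for the conservative pick


@dataclass
class SearchResult:
    theta: Hyperparameters
    p_max: float
    trace: list[tuple[float, float, float, float, float]] = field(default_factory=list)
    # trace rows: (gamma, lambda, P_raw, R, f_beta)
    grid_best: Hyperparameters | None = None
    sub_space: SearchSpace | None = None


def _module_weights(modules: Sequence[MetaModule]) -> np.ndarray:
    weights = [w for m in modules for w in m.weights.values()]
    if not weights:
        raise ValueError("no links in the meta network")
    return np.asarray(weights, dtype=float)


def evaluate_theta(
    theta: Hyperparameters,
    modules: Sequence[MetaModule],
    gold: GoldStandards,
    initial_grn: GeneRegulatoryNetwork,
    beta: float = 1.0,
    jaccard_threshold: float = 0.5,
    p_max: float | None = None,
    recall_anchor: str = "initial",
) -> tuple[float, float, float]:
    """Prune all modules at theta and score the candidate network.

    Returns ``(P_raw, R, f_beta)``.  When ``p_max`` is given, precision is
    scaled by it (capped at 1) before entering the f score; otherwise raw
    precision is used.
    """
    retained = mrf.prune_network(modules, theta)
    candidate = initial_grn.subset(retained)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty candidates are legitimate during search
        p_raw = objective.precision_regulatory(candidate.links, gold)
        recall = objective.recall_cofunctional(
            candidate, initial_grn, gold, jaccard_threshold, anchor=recall_anchor
        )
    p_scaled = min(p_raw / p_max, 1.0) if p_max else p_raw
    f = objective.f_beta_score(p_scaled, recall, beta)
    return p_raw, recall, f


def grid_search(
    modules: Sequence[MetaModule],
    gold: GoldStandards,
    initial_grn: GeneRegulatoryNetwork,
    space: SearchSpace,
    resolution: tuple[int, int] = (10, 10),
    beta: float = 1.0,
    jaccard_threshold: float = 0.5,
    recall_anchor: str = "initial",
) -> SearchResult:
    """Evaluate the (gamma, lambda) grid; return the best cell's neighbourhood.

    gamma levels sit at empirical quantiles of the link weights (clipped to
    the space), lambda levels are log-spaced.  Ties resolve to the lowest
    lambda, then the lowest gamma.  The returned ``sub_space`` is the best
    cell expanded by one grid step per axis, clipped to the space.
    """
    res_g, res_l = resolution
    if res_g < 2 or res_l < 2:
        raise ValueError("grid resolution must be >= 2 per axis")
    weights = _module_weights(modules)
    gamma_levels = np.unique(
        np.clip(np.quantile(weights, np.linspace(0, 1, res_g)), *space.gamma_range)
    )
    lam_levels = np.geomspace(space.lam_range[0], space.lam_range[1], res_l)

    rows: list[tuple[float, float, float, float]] = []  # gamma, lam, P, R
    for lam in lam_levels:
        for g in gamma_levels:
            p, r, _ = evaluate_theta(
                Hyperparameters(float(g), float(lam)), modules, gold, initial_grn,
                beta, jaccard_threshold, p_max=None, recall_anchor=recall_anchor,
            )
            rows.append((float(g), float(lam), p, r))

    p_max = max((p for _, _, p, _ in rows), default=0.0) or 1.0
    trace = []
    best = None
    best_f = -1.0
    for g, lam, p, r in rows:
        f = objective.f_beta_score(min(p / p_max, 1.0), r, beta)
        trace.append((g, lam, p, r, f))
        if f > best_f:
            best_f = f
            best = Hyperparameters(g, lam)

    gi = int(np.searchsorted(gamma_levels, best.gamma))
    li = int(np.searchsorted(lam_levels, best.lam))
    g_lo = gamma_levels[max(gi - 1, 0)]
    g_hi = gamma_levels[min(gi + 1, len(gamma_levels) - 1)]
    l_lo = lam_levels[max(li - 1, 0)]
    l_hi = lam_levels[min(li + 1, len(lam_levels) - 1)]
    sub = SearchSpace((float(g_lo), float(g_hi)), (float(l_lo), float(l_hi)))
    return SearchResult(theta=best, p_max=p_max, trace=trace, grid_best=best, sub_space=sub)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] (triangle-wave reflection)."""
    if lo == hi:
        return lo
    width = hi - lo
    t = (value - lo) % (2.0 * width)
    return lo + (t if t <= width else 2.0 * width - t)


def simulated_annealing(
    score,
    sub_space: SearchSpace,
    theta_init: Hyperparameters,
    config: AnnealingConfig = AnnealingConfig(),
    seed: int = 0,
) -> tuple[Hyperparameters, list[tuple[float, float, float, float, float]]]:
    """Metropolis refinement of theta inside the grid sub-space.

    ``score`` maps a :class:`Hyperparameters` to ``(P, R, f_beta)``; the
    annealer maximizes ``f_beta``.  Proposals are per-axis Gaussian steps
    (sigma = ``step_frac`` of the axis width) reflected at the boundaries;
    acceptance follows Metropolis on -f_beta with geometric cooling.  The
    returned theta is the conservative pick: smallest lambda (then gamma)
    among visited points within ``delta_f`` of the best visited f_beta.
    """
    if not sub_space.contains(theta_init):
        raise ValueError("theta_init outside the annealing sub-space")
    rng = np.random.default_rng(seed)

    sigma_g = config.step_frac * (sub_space.gamma_range[1] - sub_space.gamma_range[0])
    sigma_l = config.step_frac * (sub_space.lam_range[1] - sub_space.lam_range[0])

    current = theta_init
    p, r, current_f = score(current)
    visited: list[tuple[Hyperparameters, float]] = [(current, current_f)]
    trace = [(current.gamma, current.lam, p, r, current_f)]

    temp = config.t0
    for _ in range(config.n_levels):
        for _ in range(config.proposals_per_level):
            g = _reflect(current.gamma + rng.normal(0.0, sigma_g) if sigma_g > 0 else current.gamma,
                         *sub_space.gamma_range)
            lam = _reflect(current.lam + rng.normal(0.0, sigma_l) if sigma_l > 0 else current.lam,
                           *sub_space.lam_range)
            proposal = Hyperparameters(float(g), float(lam))
            p, r, f = score(proposal)
            visited.append((proposal, f))
            trace.append((proposal.gamma, proposal.lam, p, r, f))
            if f >= current_f or rng.random() < math.exp((f - current_f) / max(temp, 1e-12)):
                current, current_f = proposal, f
        temp *= config.alpha

    best_f = max(f for _, f in visited)
    band = [t for t, f in visited if f >= (1.0 - config.delta_f) * best_f]
    final = min(band, key=lambda t: (t.lam, t.gamma))
    return final, trace


def learn_theta(
    modules: Sequence[MetaModule],
    gold: GoldStandards,
    initial_grn: GeneRegulatoryNetwork,
    lam_range: tuple[float, float] = (0.001, 2.5),
    grid_resolution: tuple[int, int] = (10, 10),
    annealing: AnnealingConfig = AnnealingConfig(),
    seed: int = 0,
    beta: float = 1.0,
    jaccard_threshold: float = 0.5,
    recall_anchor: str = "initial",
) -> SearchResult:
    """Full coarse-to-fine search: grid, then simulated annealing.

    The conservative pick at the end considers the grid optimum alongside
    the annealing trajectory, so the final f_beta is never worse than the
    grid's beyond the delta_f tolerance.
    """
    space = SearchSpace.from_modules(modules, lam_range)
    grid = grid_search(
        modules, gold, initial_grn, space, grid_resolution,
        beta, jaccard_threshold, recall_anchor,
    )

    def score(theta: Hyperparameters) -> tuple[float, float, float]:
        return evaluate_theta(
            theta, modules, gold, initial_grn, beta, jaccard_threshold,
            p_max=grid.p_max, recall_anchor=recall_anchor,
        )

    theta, sa_trace = simulated_annealing(
        score, grid.sub_space, grid.theta, annealing, seed,
    )
    return SearchResult(
        theta=theta,
        p_max=grid.p_max,
        trace=grid.trace + sa_trace,
        grid_best=grid.grid_best,
        sub_space=grid.sub_space,
    )
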