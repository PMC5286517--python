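"""Seeded synthetic benchmarks with planted ground truth.

Two generators:

``generate_benchmark``
    Emulates every input the pipeline consumes — expression matrix, binding
    network, co-function network and both gold standards — around a planted
    TF -> target network.  Expression is a linear TF combination plus
    Gaussian noise, so the tree-regression stage has recoverable signal;
    the binding network mixes true links with decoys; co-function weights
    are drawn from a high Beta distribution for truly co-regulated pairs
    and a low one otherwise.

``generate_weighted_grn``
    A direct fixture for the meta-network / MRF / hyperparameter stages: a
    weighted network whose true links draw weights biased above a planted
    threshold ``t`` and decoys below it, used for parameter-recovery and
    refinement-benefit experiments without the expression stage.

Gene IDs are synthetic (``TF0001``, ``G00042``); everything is fully
deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    BindingNetwork,
    CoFunctionNetwork,
    GeneRegulatoryNetwork,
    GoldStandards,
    LinkKey,
)

__all__ = [
    "BenchmarkParams",
    "PlantedBenchmark",
    "WeightedGrnParams",
    "WeightedBenchmark",
    "generate_benchmark",
    "generate_weighted_grn",
]


@dataclass(frozen=True)
class BenchmarkParams:
    """Study conditions for the full five-input benchmark."""

    n_tfs: int = 20
    n_genes: int = 300          # total genes, TFs included
    n_conditions: int = 40
    mean_targets_per_tf: float = 12.0
    min_targets: int = 3
    regulon_overlap: float = 0.1
    coef_range: tuple[float, float] = (0.5, 1.5)   # |regulatory effect| on targets
    noise_sd: float = 2.0                          # expression noise; signal variance is ~1 per regulator
    binding_decoy_rate: float = 5.0                # decoy binding edges per true link (permissive prior)
    cofn_high: tuple[float, float] = (5.0, 2.0)    # Beta for co-regulated pairs
    cofn_low: tuple[float, float] = (1.5, 5.0)     # Beta for background pairs
    cofn_decoy_rate: float = 1.0                   # background pairs per co-regulated pair
    reg_gold_fraction: float = 0.3
    cofn_gold_fraction: float = 0.3


@dataclass
class PlantedBenchmark:
    true_network: GeneRegulatoryNetwork
    expression: pd.DataFrame
    tf_list: tuple[str, ...]
    binding: BindingNetwork
    cofn: CoFunctionNetwork
    gold: GoldStandards
    params: BenchmarkParams
    seed: int


def _gene_names(n_tfs: int, n_genes: int) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1:04d}" for i in range(n_tfs)]
    others = [f"G{i + 1:05d}" for i in range(n_genes - n_tfs)]
    return tfs, others


def _plant_links(
    rng: np.random.Generator,
    tfs: list[str],
    pool: list[str],
    mean_targets: float,
    min_targets: int,
    regulon_overlap: float = 0.1,
) -> dict[str, list[str]]:
    """Assign each TF a regulon: mostly dedicated targets, a small shared fraction.

    Regulons in real networks are largely distinct, with limited combinatorial
    control; ``regulon_overlap`` is the expected fraction of a regulon drawn
    from genes already claimed by earlier TFs.
    """
    untaken = list(pool)
    taken: list[str] = []
    targets: dict[str, list[str]] = {}
    for tf in tfs:
        k = max(min_targets, int(rng.poisson(mean_targets)))
        n_shared = min(int(rng.binomial(k, regulon_overlap)), len(taken))
        n_fresh = min(k - n_shared, len(untaken))
        chosen: list[str] = []
        if n_shared:
            idx = rng.choice(len(taken), size=n_shared, replace=False)
            chosen.extend(taken[i] for i in idx)
        if n_fresh:
            idx = rng.choice(len(untaken), size=n_fresh, replace=False)
            fresh = [untaken[i] for i in idx]
            chosen.extend(fresh)
            for g in fresh:
                untaken.remove(g)
                taken.append(g)
        if len(chosen) < min_targets:  # pool exhausted; fall back to shared picks
            extra = [g for g in taken if g not in chosen]
            idx = rng.choice(len(extra), size=min_targets - len(chosen), replace=False)
            chosen.extend(extra[i] for i in idx)
        targets[tf] = sorted(set(chosen))
    return targets


def _coregulated_true_pairs(targets_by_tf: dict[str, list[str]]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for tgts in targets_by_tf.values():
        for a, b in itertools.combinations(tgts, 2):
            pairs.add(frozenset((a, b)))
    return pairs


def _build_cofn(
    rng: np.random.Generator,
    coreg_pairs: set[frozenset],
    all_genes: list[str],
    high: tuple[float, float],
    low: tuple[float, float],
    decoy_rate: float,
) -> CoFunctionNetwork:
    cofn = CoFunctionNetwork()
    for pair in sorted(coreg_pairs, key=sorted):
        a, b = sorted(pair)
        cofn.set(a, b, float(rng.beta(*high)))
    n_decoys = int(round(decoy_rate * len(coreg_pairs)))
    added = 0
    genes = np.array(all_genes)
    while added < n_decoys:
        a, b = genes[rng.choice(len(genes), size=2, replace=False)]
        pair = frozenset((str(a), str(b)))
        if pair in coreg_pairs or pair in cofn.pairs:
            continue
        cofn.set(str(a), str(b), float(rng.beta(*low)))
        added += 1
    return cofn


def _sample_gold(
    rng: np.random.Generator,
    true_links: list[LinkKey],
    coreg_pairs: set[frozenset],
    reg_fraction: float,
    cofn_fraction: float,
) -> GoldStandards:
    n_reg = max(1, int(round(reg_fraction * len(true_links))))
    reg_idx = rng.choice(len(true_links), size=n_reg, replace=False)
    reg = frozenset(true_links[i] for i in reg_idx)
    coreg = sorted(coreg_pairs, key=sorted)
    n_cof = max(1, int(round(cofn_fraction * len(coreg))))
    cof_idx = rng.choice(len(coreg), size=n_cof, replace=False)
    cof = frozenset(coreg[i] for i in cof_idx)
    return GoldStandards(regulatory_pairs=reg, cofunction_pairs=cof)


def generate_benchmark(
    params: BenchmarkParams | None = None, seed: int = 0
) -> PlantedBenchmark:
    """Generate the five pipeline inputs around a planted network."""
    params = params or BenchmarkParams()
    if params.n_tfs < 2:
        raise ValueError("need at least 2 TFs")
    if params.n_genes < 10:
        raise ValueError("need at least 10 genes")
    if params.n_genes <= params.n_tfs:
        raise ValueError("n_genes must exceed n_tfs")
    for frac in (params.reg_gold_fraction, params.cofn_gold_fraction):
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"gold coverage fraction out of (0, 1]: {frac}")
    rng = np.random.default_rng(seed)

    tfs, others = _gene_names(params.n_tfs, params.n_genes)
    all_genes = tfs + others
    targets_by_tf = _plant_links(
        rng, tfs, others, params.mean_targets_per_tf, params.min_targets,
        params.regulon_overlap,
    )
    true_links: list[LinkKey] = sorted(
        (tf, tgt) for tf, tgts in targets_by_tf.items() for tgt in tgts
    )
    true_network = GeneRegulatoryNetwork({l: 1.0 for l in true_links})

    # expression: TFs are iid N(0, 1); targets linear combinations + noise
    lo, hi = params.coef_range
    tf_expr = rng.normal(size=(params.n_tfs, params.n_conditions))
    coefs: dict[LinkKey, float] = {}
    for tf, tgt in true_links:
        sign = -1.0 if rng.random() < 0.5 else 1.0
        coefs[(tf, tgt)] = sign * rng.uniform(lo, hi)
    expr = pd.DataFrame(
        rng.normal(scale=1.0, size=(params.n_genes, params.n_conditions)),
        index=all_genes,
        columns=[f"C{i + 1:03d}" for i in range(params.n_conditions)],
    )
    expr.iloc[: params.n_tfs] = tf_expr
    tf_row = {tf: i for i, tf in enumerate(tfs)}
    regulators_of: dict[str, list[str]] = {}
    for tf, tgt in true_links:
        regulators_of.setdefault(tgt, []).append(tf)
    for tgt, regs in regulators_of.items():
        signal = sum(coefs[(tf, tgt)] * tf_expr[tf_row[tf]] for tf in regs)
        expr.loc[tgt] = signal + rng.normal(scale=params.noise_sd, size=params.n_conditions)

    # binding: truth plus random decoy edges
    true_set = set(true_links)
    n_decoys = int(round(params.binding_decoy_rate * len(true_links)))
    decoys: set[LinkKey] = set()
    tf_arr = np.array(tfs)
    gene_arr = np.array(all_genes)
    while len(decoys) < n_decoys:
        tf = str(tf_arr[rng.integers(len(tf_arr))])
        tgt = str(gene_arr[rng.integers(len(gene_arr))])
        if tf == tgt or (tf, tgt) in true_set or (tf, tgt) in decoys:
            continue
        decoys.add((tf, tgt))
    binding = BindingNetwork.from_pairs(true_set | decoys)

    coreg_pairs = _coregulated_true_pairs(targets_by_tf)
    cofn = _build_cofn(
        rng, coreg_pairs, all_genes, params.cofn_high, params.cofn_low,
        params.cofn_decoy_rate,
    )
    gold = _sample_gold(
        rng, true_links, coreg_pairs, params.reg_gold_fraction, params.cofn_gold_fraction
    )
    return PlantedBenchmark(
        true_network=true_network,
        expression=expr,
        tf_list=tuple(tfs),
        binding=binding,
        cofn=cofn,
        gold=gold,
        params=params,
        seed=seed,
    )


@dataclass(frozen=True)
class WeightedGrnParams:
    """Study conditions for the direct weighted-network fixture."""

    n_tfs: int = 15
    n_genes: int = 200
    mean_targets_per_tf: float = 10.0
    min_targets: int = 3
    regulon_overlap: float = 0.1
    decoy_rate: float = 1.0            # decoy links per true link, per TF
    threshold: float = 0.5             # planted weight threshold t
    separation: float = 0.0            # weight gap around t; 0 = overlapping
    true_beta: tuple[float, float] = (5.0, 2.0)
    decoy_beta: tuple[float, float] = (2.0, 5.0)
    cofn_high: tuple[float, float] = (5.0, 2.0)
    cofn_low: tuple[float, float] = (1.5, 5.0)
    cofn_decoy_rate: float = 1.0
    reg_gold_fraction: float = 0.3
    cofn_gold_fraction: float = 0.3


@dataclass
class WeightedBenchmark:
    grn: GeneRegulatoryNetwork
    cofn: CoFunctionNetwork
    gold: GoldStandards
    true_links: frozenset[LinkKey]
    threshold: float
    params: WeightedGrnParams = field(repr=False)
    seed: int = 0


def generate_weighted_grn(
    params: WeightedGrnParams | None = None, seed: int = 0
) -> WeightedBenchmark:
    """Plant a weighted network with true links above and decoys below ``t``.

    With ``separation == 0`` the two Beta weight distributions overlap
    around the threshold; a positive separation maps true weights into
    ``[t + sep/2, 1]`` and decoy weights into ``[0, t - sep/2]``
    (well-separated regime for parameter-recovery experiments).
    """
    params = params or WeightedGrnParams()
    t = params.threshold
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    if not (0.0 <= params.separation < min(t, 1 - t) * 2):
        raise ValueError("separation incompatible with the threshold")
    rng = np.random.default_rng(seed)

    tfs, others = _gene_names(params.n_tfs, params.n_genes)
    targets_by_tf = _plant_links(
        rng, tfs, others, params.mean_targets_per_tf, params.min_targets,
        params.regulon_overlap,
    )
    true_links = sorted(
        (tf, tgt) for tf, tgts in targets_by_tf.items() for tgt in tgts
    )
    true_set = set(true_links)

    half_gap = params.separation / 2.0

    def true_weight() -> float:
        b = float(rng.beta(*params.true_beta))
        if params.separation > 0:
            return t + half_gap + (1.0 - t - half_gap) * b
        return b

    def decoy_weight() -> float:
        b = float(rng.beta(*params.decoy_beta))
        if params.separation > 0:
            return (t - half_gap) * b
        return b

    links: dict[LinkKey, float] = {l: true_weight() for l in true_links}
    others_arr = np.array(others)
    for tf in tfs:
        n_dec = int(round(params.decoy_rate * len(targets_by_tf[tf])))
        added = 0
        while added < n_dec:
            tgt = str(others_arr[rng.integers(len(others_arr))])
            if (tf, tgt) in links:
                continue
            links[(tf, tgt)] = decoy_weight()
            added += 1
    grn = GeneRegulatoryNetwork(links)

    coreg_pairs = _coregulated_true_pairs(targets_by_tf)
    cofn = _build_cofn(
        rng, coreg_pairs, tfs + others, params.cofn_high, params.cofn_low,
        params.cofn_decoy_rate,
    )
    gold = _sample_gold(
        rng, true_links, coreg_pairs, params.reg_gold_fraction, params.cofn_gold_fraction
    )
    return WeightedBenchmark(
        grn=grn,
        cofn=cofn,
        gold=gold,
        true_links=frozenset(true_links),
        threshold=t,
        params=params,
        seed=seed,
    )
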