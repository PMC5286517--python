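"""Hold-out ensemble of independently trained pruning models.

N rounds of 0.632 hold-out validation: each round samples 63.2% of the
meta-network modules (without replacement) together with the gold-standard
entries that fall inside them, learns theta on that training material, and
applies the learned model to *all* modules so the ensemble vote is defined
for every link.  The remaining modules form the round's test set, on which
gold-standard enrichment is reported.  The final network keeps a link when
the fraction of rounds retaining it exceeds the vote threshold eps_p
(default 0.5, i.e. more than half the models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hyperopt, mrf, objective
from .datatypes import (
    GeneRegulatoryNetwork,
    GoldStandards,
    Hyperparameters,
    LinkKey,
    MetaModule,
)
from .grn_init import derive_seed

__all__ = [
    "HoldoutRound",
    "EnsembleResult",
    "holdout_split",
    "restrict_gold",
    "train_round",
    "aggregate",
    "run_ensemble",
]


@dataclass
class HoldoutRound:
    index: int
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    theta: Hyperparameters
    retained: frozenset[LinkKey]
    test_enrichment: tuple[float, float] | None = None  # (fold change, p-value)


@dataclass
class EnsembleResult:
    likelihood: dict[LinkKey, float]
    epsilon: float
    final_links: frozenset[LinkKey] = field(init=False)
    n_rounds: int = 0

    def __post_init__(self):
        self.final_links = frozenset(
            l for l, v in self.likelihood.items() if v > self.epsilon
        )


def holdout_split(
    modules: Sequence[MetaModule], fraction: float, rng: np.random.Generator
) -> tuple[list[MetaModule], list[MetaModule]]:
    """Sample round(fraction * M) modules without replacement as the training set."""
    m = len(modules)
    if m < 2:
        raise ValueError("need at least 2 modules to split")
    n_train = int(round(fraction * m))
    if n_train < 1 or n_train >= m:
        raise ValueError(
            f"fraction {fraction} leaves an empty train or test set for {m} modules"
        )
    idx = rng.permutation(m)
    train_idx = sorted(idx[:n_train].tolist())
    test_idx = sorted(idx[n_train:].tolist())
    return [modules[i] for i in train_idx], [modules[i] for i in test_idx]


def restrict_gold(gold: GoldStandards, modules: Sequence[MetaModule]) -> GoldStandards:
    """Gold entries that fall inside the given modules.

    A regulatory pair belongs iff it is one of the modules' links; a
    co-annotation pair belongs iff both genes are targets within the modules.
    """
    links = {n for m in modules for n in m.nodes}
    genes = {t for _, t in links}
    return GoldStandards(
        regulatory_pairs=frozenset(p for p in gold.regulatory_pairs if p in links),
        cofunction_pairs=frozenset(
            p for p in gold.cofunction_pairs if p <= genes
        ),
    )


def train_round(
    index: int,
    modules: Sequence[MetaModule],
    gold: GoldStandards,
    initial_grn: GeneRegulatoryNetwork,
    fraction: float = 0.632,
    seed: int = 0,
    **hyperopt_kwargs,
) -> HoldoutRound:
    """One hold-out round: split, learn theta on the train part, vote on everything."""
    round_seed = derive_seed(seed, f"round-{index}")
    rng = np.random.default_rng(round_seed)
    train, test = holdout_split(modules, fraction, rng)
    train_gold = restrict_gold(gold, train)
    test_gold = restrict_gold(gold, test)
    train_links = {n for m in train for n in m.nodes}
    initial_train = initial_grn.subset(train_links)

    result = hyperopt.learn_theta(
        train, train_gold, initial_train, seed=round_seed, **hyperopt_kwargs
    )
    retained = frozenset(mrf.prune_network(modules, result.theta))

    enrichment = _test_enrichment(retained, test, test_gold)
    return HoldoutRound(
        index=index,
        train_ids=tuple(m.module_id for m in train),
        test_ids=tuple(m.module_id for m in test),
        theta=result.theta,
        retained=retained,
        test_enrichment=enrichment,
    )


def _test_enrichment(
    retained: frozenset[LinkKey],
    test_modules: Sequence[MetaModule],
    test_gold: GoldStandards,
) -> tuple[float, float] | None:
    """Regulatory-gold enrichment of the retained links within the test modules.

    Background: all links of the test modules.  None when the table is
    degenerate (no retained test links or no gold in the test split).
    """
    test_links = {n for m in test_modules for n in m.nodes}
    pred = retained & test_links
    hits_bg = len(test_links & test_gold.regulatory_pairs)
    if not pred or hits_bg == 0:
        return None
    hits = len(pred & test_gold.regulatory_pairs)
    return objective.fisher_enrichment(hits, len(pred), hits_bg, len(test_links))


def aggregate(rounds: Sequence[HoldoutRound], epsilon: float = 0.5) -> EnsembleResult:
    """Vote fraction per link; keep links retained by strictly more than eps_p of rounds."""
    if not rounds:
        raise ValueError("no rounds to aggregate")
    counts: dict[LinkKey, int] = {}
    for rnd in rounds:
        for link in rnd.retained:
            counts[link] = counts.get(link, 0) + 1
    n = len(rounds)
    likelihood = {link: c / n for link, c in counts.items()}
    result = EnsembleResult(likelihood=likelihood, epsilon=epsilon)
    result.n_rounds = n
    return result


def run_ensemble(
    modules: Sequence[MetaModule],
    gold: GoldStandards,
    initial_grn: GeneRegulatoryNetwork,
    n_rounds: int = 100,
    fraction: float = 0.632,
    epsilon: float = 0.5,
    seed: int = 0,
    **hyperopt_kwargs,
) -> tuple[EnsembleResult, list[HoldoutRound]]:
    """Train ``n_rounds`` independent models and aggregate their votes."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rounds = []
    for i in range(n_rounds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse splits legitimately trigger
            rounds.append(
                train_round(
                    i, modules, gold, initial_grn,
                    fraction=fraction, seed=seed, **hyperopt_kwargs,
                )
            )
    return aggregate(rounds, epsilon), rounds
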