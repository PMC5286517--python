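"""Semi-supervised scoring of a pruned network against sparse gold standards.

Regulatory gold standards (curated TF -> target pairs) measure precision;
co-annotated gene pairs (e.g. a GO benchmark) measure how much supported
co-regulation the pruner retains.  Because curated maps are sparse, raw
precision is scaled so its observed maximum over the candidate set becomes 1,
and the two surfaces are combined with an f_beta score.  Co-regulation of a
gene pair means their regulator sets overlap with Jaccard coefficient
strictly above the threshold (default 50%).

Enrichment of a prediction set over the fully connected background is
assessed by fold change and a one-sided Fisher's exact test.
"""

from __future__ import annotations

import warnings
from typing import Iterable

from scipy.stats import fisher_exact

from .datatypes import GeneRegulatoryNetwork, GoldStandards, LinkKey

__all__ = [
    "coregulated_pairs",
    "precision_regulatory",
    "recall_cofunctional",
    "f_beta_score",
    "fisher_enrichment",
]


def coregulated_pairs(
    grn: GeneRegulatoryNetwork, jaccard_threshold: float = 0.5
) -> set[frozenset]:
    """Unordered gene pairs whose regulator sets exceed the Jaccard threshold.

    A pair (g, g') qualifies iff |R_g & R_g'| / |R_g | R_g'| is strictly
    greater than ``jaccard_threshold``; genes with no regulators never
    qualify.
    """
    if not (0.0 <= jaccard_threshold <= 1.0):
        raise ValueError(f"jaccard_threshold must be in [0, 1], got {jaccard_threshold}")
    regsets = grn.regulator_sets()
    # candidates: only pairs sharing at least one regulator can pass a
    # positive threshold; enumerate via per-regulator target groups
    by_reg: dict[str, list[str]] = {}
    for reg, tgt in grn.links:
        by_reg.setdefault(reg, []).append(tgt)
    candidates: set[frozenset] = set()
    for targets in by_reg.values():
        targets = sorted(set(targets))
        for i in range(len(targets)):
            for j in range(i + 1, len(targets)):
                candidates.add(frozenset((targets[i], targets[j])))
    out: set[frozenset] = set()
    for pair in candidates:
        g, g2 = tuple(pair)
        ra, rb = regsets[g], regsets[g2]
        jac = len(ra & rb) / len(ra | rb)
        if jac > jaccard_threshold:
            out.add(pair)
    return out


def precision_regulatory(
    predicted: Iterable[LinkKey],
    gold: GoldStandards,
    restrict_to_gold_regulators: bool = True,
) -> float:
    """Fraction of predicted links found in the regulatory gold standard.

    With ``restrict_to_gold_regulators`` (default), the denominator counts
    only predictions whose regulator appears in the gold standard at all:
    sparse curated maps say nothing about the other regulators, so counting
    them would only dilute the signal.
    """
    predicted = set(predicted)
    if restrict_to_gold_regulators:
        regs = gold.gold_regulators
        evaluable = {l for l in predicted if l[0] in regs}
    else:
        evaluable = predicted
    if not evaluable:
        warnings.warn("no gold-evaluable predictions; precision reported as 0", stacklevel=2)
        return 0.0
    return len(evaluable & gold.regulatory_pairs) / len(evaluable)


def recall_cofunctional(
    predicted_grn: GeneRegulatoryNetwork,
    initial_grn: GeneRegulatoryNetwork,
    gold: GoldStandards,
    jaccard_threshold: float = 0.5,
    anchor: str = "initial",
) -> float:
    """Recovery of co-annotated co-regulated gene pairs.

    The reference set (``anchor="initial"``, default) holds the gene pairs
    that are co-regulated in the *initial* network and co-annotated in the
    gold standard — the supported co-regulation available before pruning.
    Recall is the fraction of that set still co-regulated in the pruned
    network.  ``anchor="benchmark"`` references the whole co-annotation
    benchmark instead.

    The numerator is intersected with the reference set: pruning can also
    *create* co-regulated pairs (removing a regulator raises a pair's
    Jaccard coefficient), and such new pairs are not recoveries.
    """
    extra = set(predicted_grn.links) - set(initial_grn.links)
    if extra:
        raise ValueError(f"predicted network is not a subset of the initial one: {sorted(extra)[:3]}")
    if anchor == "initial":
        reference = coregulated_pairs(initial_grn, jaccard_threshold) & gold.cofunction_pairs
    elif anchor == "benchmark":
        reference = set(gold.cofunction_pairs)
    else:
        raise ValueError(f"unknown recall anchor: {anchor!r}")
    if not reference:
        warnings.warn("no co-annotated co-regulated pairs in the reference set; recall reported as 0",
                      stacklevel=2)
        return 0.0
    num = len(coregulated_pairs(predicted_grn, jaccard_threshold) & reference)
    return num / len(reference)


def f_beta_score(p_scaled: float, recall: float, beta: float = 1.0) -> float:
    """f_beta = (1 + beta^2) P R / (beta^2 P + R); 0 when both are 0."""
    for v in (p_scaled, recall):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"precision/recall out of [0, 1]: {v}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if p_scaled == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * p_scaled * recall / (b2 * p_scaled + recall)


def fisher_enrichment(
    hits_pred: int, n_pred: int, hits_bg: int, n_bg: int
) -> tuple[float, float]:
    """Fold change and one-sided Fisher p-value of predictions vs. background.

    The background is the full candidate universe containing the prediction
    set (e.g. the fully connected regulator x gene network); the 2x2 table
    contrasts predictions with the remaining non-predicted candidates.
    """
    if not (0 <= hits_pred <= n_pred):
        raise ValueError("hits_pred must lie in [0, n_pred]")
    if not (0 <= hits_bg <= n_bg):
        raise ValueError("hits_bg must lie in [0, n_bg]")
    if n_bg < n_pred or hits_bg < hits_pred:
        raise ValueError("background must contain the prediction set")
    if hits_bg == 0:
        raise ValueError("background hit count is 0: fold change undefined")
    if n_pred == 0:
        raise ValueError("empty prediction set")
    fold = (hits_pred / n_pred) / (hits_bg / n_bg)
    table = [
        [hits_pred, n_pred - hits_pred],
        [hits_bg - hits_pred, (n_bg - n_pred) - (hits_bg - hits_pred)],
    ]
    _, p = fisher_exact(table, alternative="greater")
    return fold, float(p)
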