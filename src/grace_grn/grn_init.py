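"""Initial integrative GRN construction.

The initial network combines two genome-wide evidence layers:

1. an expression-based network from per-target randomized tree-ensemble
   regression (GENIE3-style): each gene's expression profile is regressed on
   all transcription factors and the ensemble importance of each TF scores
   the candidate link TF -> target;
2. a DNA-binding prior network (pre-built edge list).

Importances are rank-normalized with an empirical CDF over *all* TF-target
scores, the top fraction (default 5%) is kept, and the surviving links are
intersected with the binding network.
"""

from __future__ import annotations

import warnings
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datatypes import BindingNetwork, GeneRegulatoryNetwork, LinkKey

__all__ = [
    "preprocess_expression",
    "infer_importance_network",
    "ecdf_filter",
    "intersect_with_binding",
    "build_initial_grn",
    "derive_seed",
]


def derive_seed(global_seed: int, token: str | int) -> int:
    """Stable per-item seed, independent of iteration order and platform."""
    h = zlib.crc32(f"{global_seed}:{token}".encode())
    return int(h % (2**31 - 1))


def preprocess_expression(
    raw: pd.DataFrame,
    replicate_map: Mapping[str, str] | None = None,
    variance_quantile: float = 0.5,
) -> pd.DataFrame:
    """Average replicate columns and drop low-variance genes.

    Parameters
    ----------
    raw:
        Expression matrix, genes x conditions (index = gene IDs, columns =
        condition IDs), already normalized upstream.
    replicate_map:
        Condition ID -> replicate-group label.  Every column must be mapped;
        members of a group are averaged into one column named by the label.
        ``None`` means every condition is its own group.
    variance_quantile:
        Fraction in [0, 1); genes whose across-column variance falls strictly
        below this sample quantile (linear interpolation) of all gene
        variances are removed.  0 keeps everything.
    """
    if raw.index.has_duplicates:
        raise ValueError("duplicate gene IDs in expression matrix")
    if raw.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if not (0.0 <= variance_quantile < 1.0):
        raise ValueError(f"variance_quantile must be in [0, 1), got {variance_quantile}")

    if replicate_map is not None:
        missing = [c for c in raw.columns if c not in replicate_map]
        if missing:
            raise ValueError(f"conditions missing from replicate_map: {missing[:5]}")
        groups = sorted(set(replicate_map.values()))
        empty = [g for g in groups if not any(replicate_map[c] == g for c in raw.columns)]
        if empty:  # pragma: no cover - unreachable when groups come from the map
            raise ValueError(f"replicate groups with zero members: {empty}")
        averaged = pd.DataFrame(
            {g: raw.loc[:, [c for c in raw.columns if replicate_map[c] == g]].mean(axis=1)
             for g in groups},
            index=raw.index,
        )
    else:
        averaged = raw.copy()

    if averaged.shape[1] < 2:
        raise ValueError("need at least 2 conditions after replicate averaging")

    variances = averaged.var(axis=1, ddof=1).to_numpy()
    if variance_quantile > 0:
        cutoff = float(np.quantile(variances, variance_quantile))
        keep = variances >= cutoff
    else:
        keep = np.ones(len(variances), dtype=bool)
    filtered = averaged.loc[keep]
    if filtered.empty:
        raise ValueError("no genes left after variance filtering")
    return filtered


def infer_importance_network(
    expr: pd.DataFrame,
    tf_list: Iterable[str],
    n_trees: int = 1000,
    seed: int = 0,
    max_features: float | str = "sqrt",
) -> list[tuple[str, str, float]]:
    """Per-target tree-ensemble regression importances for every TF-target pair.

    For each target gene, a random-forest regression of its expression on all
    TFs (excluding the target itself when it is a TF) yields one non-negative
    importance per TF: the total impurity (variance) reduction over splits,
    averaged over trees.  Constant targets produce all-zero importances.
    Results are deterministic given ``seed``; each target uses a seed derived
    from the target ID so they are independent of iteration order.
    """
    tfs = sorted(set(tf_list))
    if not tfs:
        raise ValueError("tf_list is empty")
    missing = [tf for tf in tfs if tf not in expr.index]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing[:5]}")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    tf_data = expr.loc[tfs].to_numpy(dtype=float)
    tf_index = {tf: i for i, tf in enumerate(tfs)}
    scores: list[tuple[str, str, float]] = []
    for target in expr.index:
        y = expr.loc[target].to_numpy(dtype=float)
        predictors = [tf for tf in tfs if tf != target]
        if not predictors:
            continue
        cols = [tf_index[tf] for tf in predictors]
        X = tf_data[cols].T
        if np.var(y) == 0.0:
            imp = np.zeros(len(predictors))
        else:
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=derive_seed(seed, target),
                n_jobs=1,
            )
            forest.fit(X, y)
            # unnormalized impurity reduction keeps scores comparable
            # across targets with different explainable variance
            imp = np.mean(
                [t.tree_.compute_feature_importances(normalize=False)
                 for t in forest.estimators_],
                axis=0,
            )
        scores.extend((tf, target, float(v)) for tf, v in zip(predictors, imp))
    return scores


def ecdf_filter(
    scores: Sequence[tuple[str, str, float]],
    keep_fraction: float = 0.05,
) -> dict[LinkKey, float]:
    """Rank-normalize raw importances and keep the top fraction.

    Each score is mapped to its empirical CDF value over *all* scores,
    ECDF(x) = #{scores <= x} / n, which becomes the link weight v in (0, 1].
    Links with ECDF value strictly above ``1 - keep_fraction`` are returned.
    Ties share an ECDF value and are kept or dropped together, so the output
    may slightly exceed ``keep_fraction * n``.
    """
    if not scores:
        raise ValueError("empty score list")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    raw = np.array([s for _, _, s in scores], dtype=float)
    order = np.sort(raw)
    ecdf = np.searchsorted(order, raw, side="right") / len(raw)
    cut = 1.0 - keep_fraction
    return {
        (reg, tgt): float(e)
        for (reg, tgt, _), e in zip(scores, ecdf)
        if e > cut and reg != tgt
    }


def intersect_with_binding(
    expr_links: Mapping[LinkKey, float],
    binding: BindingNetwork,
    keep_unmatched_regulators: bool = False,
) -> GeneRegulatoryNetwork:
    """Keep expression links supported by the DNA-binding prior, weights preserved.

    With ``keep_unmatched_regulators``, links whose regulator has no binding
    data at all pass through unfiltered (the prior cannot speak against
    them); the default is the strict intersection.
    """
    if keep_unmatched_regulators:
        known = {r for r, _ in binding.edges}
        kept = {k: w for k, w in expr_links.items()
                if k in binding or k[0] not in known}
    else:
        kept = {k: w for k, w in expr_links.items() if k in binding}
    if not kept:
        warnings.warn("expression network and binding network share no links", stacklevel=2)
    return GeneRegulatoryNetwork(kept)


def build_initial_grn(
    expr: pd.DataFrame,
    tf_list: Iterable[str],
    binding: BindingNetwork,
    keep_fraction: float = 0.05,
    n_trees: int = 1000,
    seed: int = 0,
) -> GeneRegulatoryNetwork:
    """Full initial-network stage: regression -> ECDF top fraction -> binding filter."""
    scores = infer_importance_network(expr, tf_list, n_trees=n_trees, seed=seed)
    links = ecdf_filter(scores, keep_fraction=keep_fraction)
    return intersect_with_binding(links, binding)
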