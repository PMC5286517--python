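"""End-to-end orchestration: config, stage logging, and the full run.

The pipeline chains the stages

    expression + binding  ->  initial network       (grn_init)
    + co-function network ->  spanning-tree modules  (meta_network)
    + gold standards      ->  hold-out ensemble      (ensemble / hyperopt / mrf)

and writes the final network, per-link vote likelihoods, per-round
hyperparameters and a JSON run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, ensemble, grn_init, io, meta_network

logger = logging.getLogger("grace")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration for a full run (YAML-loadable)."""

    # input paths
    expression: str
    tf_list: str
    binding: str
    cofunction: str
    gold_regulatory: str
    gold_cofunction: str
    out_dir: str = "grace_out"
    # initial-network stage
    keep_fraction: float = 0.05
    n_trees: int = 1000
    variance_quantile: float = 0.5
    # objective
    jaccard_threshold: float = 0.5
    beta: float = 1.0
    # hyperparameter search
    lam_min: float = 0.001
    lam_max: float = 2.5
    grid_resolution: int = 10
    sa_levels: int = 50
    sa_proposals: int = 4
    # ensemble
    n_rounds: int = 100
    fraction: float = 0.632
    epsilon: float = 0.5
    seed: int = 0
    meta_combination: str = "product"

    def __post_init__(self):
        checks = [
            (0.0 < self.keep_fraction <= 1.0, "keep_fraction in (0, 1]"),
            (self.n_trees >= 1, "n_trees >= 1"),
            (0.0 <= self.variance_quantile < 1.0, "variance_quantile in [0, 1)"),
            (0.0 <= self.jaccard_threshold <= 1.0, "jaccard_threshold in [0, 1]"),
            (self.beta > 0, "beta > 0"),
            (0.0 < self.lam_min <= self.lam_max, "0 < lam_min <= lam_max"),
            (self.grid_resolution >= 2, "grid_resolution >= 2"),
            (self.n_rounds >= 1, "n_rounds >= 1"),
            (0.0 < self.fraction < 1.0, "fraction in (0, 1)"),
            (0.0 <= self.epsilon < 1.0, "epsilon in [0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: require {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages and write artifacts; returns the output paths."""
    import errno

    for path in (config.expression, config.tf_list, config.binding,
                 config.cofunction, config.gold_regulatory, config.gold_cofunction):
        if not Path(path).is_file():
            raise FileNotFoundError(errno.ENOENT, "missing input file", str(path))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/3: initial network inference")
    expr = io.read_expression(config.expression)
    expr = grn_init.preprocess_expression(expr, variance_quantile=config.variance_quantile)
    tfs = [tf for tf in io.read_tf_list(config.tf_list) if tf in expr.index]
    binding = io.read_binding(config.binding)
    scores = grn_init.infer_importance_network(
        expr, tfs, n_trees=config.n_trees, seed=config.seed
    )
    expr_links = grn_init.ecdf_filter(scores, keep_fraction=config.keep_fraction)
    initial = grn_init.intersect_with_binding(expr_links, binding)
    logger.info(
        "  %d TF-target scores -> %d expression links -> %d initial links",
        len(scores), len(expr_links), len(initial),
    )

    logger.info("stage 2/3: meta network and modules")
    cofn = io.read_cofunction(config.cofunction)
    modules = meta_network.build_modules(initial, cofn, config.meta_combination)
    n_single = sum(1 for m in modules if len(m) == 1)
    logger.info("  %d modules (%d single-link)", len(modules), n_single)

    logger.info("stage 3/3: hold-out ensemble (%d rounds)", config.n_rounds)
    gold = io.read_gold_standards(config.gold_regulatory, config.gold_cofunction)
    from .hyperopt import AnnealingConfig

    result, rounds = ensemble.run_ensemble(
        modules, gold, initial,
        n_rounds=config.n_rounds,
        fraction=config.fraction,
        epsilon=config.epsilon,
        seed=config.seed,
        beta=config.beta,
        jaccard_threshold=config.jaccard_threshold,
        lam_range=(config.lam_min, config.lam_max),
        grid_resolution=(config.grid_resolution, config.grid_resolution),
        annealing=AnnealingConfig(
            n_levels=config.sa_levels, proposals_per_level=config.sa_proposals
        ),
    )
    logger.info(
        "  retained %d of %d initial links (%.1f%%)",
        len(result.final_links), len(initial),
        100.0 * len(result.final_links) / max(len(initial), 1),
    )

    paths = {
        "initial_network": out / "initial_network.tsv",
        "modules": out / "modules.tsv",
        "likelihoods": out / "link_likelihoods.tsv",
        "final_network": out / "final_network.tsv",
        "rounds": out / "rounds.tsv",
        "manifest": out / "manifest.json",
    }
    io.write_network(initial, paths["initial_network"])
    io.write_modules(modules, paths["modules"])
    io.write_likelihoods(result.likelihood, paths["likelihoods"])
    io.write_network(initial.subset(result.final_links), paths["final_network"])
    round_rows = [
        (r.index, f"{r.theta.gamma:.10g}", f"{r.theta.lam:.10g}",
         f"{r.test_enrichment[0]:.6g}" if r.test_enrichment else "NA",
         f"{r.test_enrichment[1]:.6g}" if r.test_enrichment else "NA")
        for r in rounds
    ]
    io.write_edge_list(
        round_rows, paths["rounds"],
        header=("round", "gamma", "lambda", "test_fold_change", "test_p_value"),
    )
    io.write_manifest(
        {
            "config": config.to_dict(),
            "version": __version__,
            "counts": {
                "tf_target_scores": len(scores),
                "expression_links": len(expr_links),
                "initial_links": len(initial),
                "modules": len(modules),
                "final_links": len(result.final_links),
            },
        },
        paths["manifest"],
    )
    return paths
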