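"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV: expression matrices carry a header row of condition IDs
and a first column of gene IDs; networks are 2- or 3-column edge lists
(regulator, target[, weight]); gene-set benchmarks may arrive as GMT files
(set name, description, members) which are expanded to within-set pairs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import (
    BindingNetwork,
    CoFunctionNetwork,
    GeneRegulatoryNetwork,
    GoldStandards,
    LinkKey,
    MetaModule,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_tf_list",
    "write_tf_list",
    "read_network",
    "write_network",
    "read_binding",
    "read_cofunction",
    "read_gold_standards",
    "expand_gmt_to_pairs",
    "write_modules",
    "write_marginals",
    "write_likelihoods",
    "write_search_trace",
    "write_manifest",
    "write_benchmark",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x conditions TSV with a header row and gene IDs in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    if df.empty:
        raise ValueError(f"empty expression matrix: {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_edge_list(
    path: str | Path,
    weighted: bool = False,
    header: bool = False,
) -> list[tuple]:
    """Parse a 2- or 3-column TSV edge list with per-line validation.

    Duplicate edges are collapsed keeping the maximum weight (a warning is
    emitted).  Weighted rows must carry a third column parseable as a real
    in [0, 1].
    """
    expected = 3 if weighted else 2
    rows: dict[tuple[str, str], float] = {}
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene ID")
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from exc
                if not (0.0 <= w <= 1.0):
                    raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            else:
                w = 1.0
            key = (a, b)
            if key in rows:
                duplicates += 1
                rows[key] = max(rows[key], w)
            else:
                rows[key] = w
    if duplicates:
        warnings.warn(f"{path}: collapsed {duplicates} duplicate edges (kept max weight)",
                      stacklevel=2)
    if weighted:
        return [(a, b, w) for (a, b), w in rows.items()]
    return [(a, b) for (a, b) in rows]


def write_edge_list(
    edges: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for edge in edges:
            fh.write("\t".join(str(x) for x in edge) + "\n")


def read_tf_list(path: str | Path) -> list[str]:
    """One regulator gene ID per line."""
    with open(path) as fh:
        tfs = [line.strip() for line in fh if line.strip()]
    if not tfs:
        raise ValueError(f"empty TF list: {path}")
    return tfs


def write_tf_list(tfs: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in tfs:
            fh.write(f"{tf}\n")


def read_network(path: str | Path, header: bool = False) -> GeneRegulatoryNetwork:
    """Weighted 3-column edge list -> network."""
    rows = read_edge_list(path, weighted=True, header=header)
    return GeneRegulatoryNetwork({(r, t): w for r, t, w in rows})


def write_network(grn: GeneRegulatoryNetwork, path: str | Path) -> None:
    rows = sorted((r, t, f"{w:.10g}") for (r, t), w in grn.links.items())
    write_edge_list(rows, path)


def read_binding(path: str | Path, header: bool = False) -> BindingNetwork:
    return BindingNetwork.from_pairs(read_edge_list(path, weighted=False, header=header))


def read_cofunction(path: str | Path, header: bool = False) -> CoFunctionNetwork:
    cofn = CoFunctionNetwork()
    for a, b, w in read_edge_list(path, weighted=True, header=header):
        if a == b:
            continue
        existing = cofn.pairs.get(frozenset((a, b)))
        cofn.set(a, b, max(w, existing) if existing is not None else w)
    return cofn


def read_gold_standards(
    regulatory_path: str | Path,
    cofunction_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    header: bool = False,
) -> GoldStandards:
    """Curated regulator -> target pairs plus co-annotated gene pairs.

    Co-annotation may come from a 2-column pair list, a GMT gene-set file,
    or both (union).
    """
    reg = read_edge_list(regulatory_path, weighted=False, header=header)
    cof: set[frozenset] = set()
    if cofunction_path is not None:
        cof |= {frozenset(p) for p in read_edge_list(cofunction_path, header=header)
                if p[0] != p[1]}
    if gmt_path is not None:
        cof |= expand_gmt_to_pairs(gmt_path)
    return GoldStandards.build(reg, cof)


def expand_gmt_to_pairs(path: str | Path) -> set[frozenset]:
    """All unordered within-set pairs, unioned over the sets of a GMT file."""
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, members")
            members = sorted({m.strip() for m in fields[2:] if m.strip()})
            if len(members) < 2:
                warnings.warn(f"{path}:{lineno}: gene set {fields[0]!r} has < 2 members, skipped",
                              stacklevel=2)
                continue
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset((members[i], members[j])))
    return pairs


def write_modules(modules: Sequence[MetaModule], path: str | Path) -> None:
    rows = [("module_id", "regulator", "target", "weight")]
    for m in modules:
        for reg, tgt in m.nodes:
            rows.append((m.module_id, reg, tgt, f"{m.weights[(reg, tgt)]:.10g}"))
    write_edge_list(rows[1:], path, header=rows[0])


def write_marginals(
    marginals: Mapping[LinkKey, float],
    weights: Mapping[LinkKey, float],
    clamped: set[LinkKey],
    module_ids: Mapping[LinkKey, int],
    path: str | Path,
) -> None:
    header = ("regulator", "target", "weight", "marginal", "clamped", "module_id")
    rows = [
        (r, t, f"{weights[(r, t)]:.10g}", f"{p:.10g}",
         int((r, t) in clamped), module_ids[(r, t)])
        for (r, t), p in sorted(marginals.items())
    ]
    write_edge_list(rows, path, header=header)


def write_likelihoods(likelihood: Mapping[LinkKey, float], path: str | Path) -> None:
    header = ("regulator", "target", "likelihood")
    rows = [(r, t, f"{v:.10g}") for (r, t), v in sorted(likelihood.items())]
    write_edge_list(rows, path, header=header)


def write_search_trace(
    trace: Iterable[tuple[float, float, float, float, float]], path: str | Path
) -> None:
    """Hyperparameter-search audit trail: one (gamma, lambda, P, R, f) row per evaluation."""
    header = ("gamma", "lambda", "precision", "recall", "f_beta")
    rows = [tuple(f"{v:.10g}" for v in row) for row in trace]
    write_edge_list(rows, path, header=header)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_benchmark(bench, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic benchmark's five inputs (plus truth) as pipeline files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "tf_list": out / "tf_list.txt",
        "binding": out / "binding.tsv",
        "cofunction": out / "cofunction.tsv",
        "gold_regulatory": out / "gold_regulatory.tsv",
        "gold_cofunction": out / "gold_cofunction.tsv",
        "true_network": out / "true_network.tsv",
    }
    write_expression(bench.expression, paths["expression"])
    write_tf_list(bench.tf_list, paths["tf_list"])
    write_edge_list(sorted(bench.binding.edges), paths["binding"])
    write_edge_list(
        sorted((*sorted(p), f"{w:.10g}") for p, w in bench.cofn.pairs.items()),
        paths["cofunction"],
    )
    write_edge_list(sorted(bench.gold.regulatory_pairs), paths["gold_regulatory"])
    write_edge_list(
        sorted(tuple(sorted(p)) for p in bench.gold.cofunction_pairs),
        paths["gold_cofunction"],
    )
    write_network(bench.true_network, paths["true_network"])
    return paths
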