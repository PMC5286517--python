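"""Shared domain containers for the network-refinement pipeline.

A regulatory link is identified by an ordered ``(regulator, target)`` pair of
gene IDs; its confidence weight (an ECDF-normalized importance, written
``v`` throughout) lives in ``(0, 1]``.  The meta network re-represents links
as nodes, connected whenever two links share a regulator, and decomposes
into per-regulator modules reduced to maximum spanning trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

__all__ = [
    "LinkKey",
    "GeneRegulatoryNetwork",
    "BindingNetwork",
    "CoFunctionNetwork",
    "GoldStandards",
    "Hyperparameters",
    "MetaEdge",
    "MetaModule",
]

#: A regulatory link identity: (regulator gene ID, target gene ID).
LinkKey = tuple[str, str]


class GeneRegulatoryNetwork:
    """A weighted directed TF -> target network.

    Parameters
    ----------
    links:
        Mapping from ``(regulator, target)`` to confidence weight in [0, 1].
        Self-links are rejected; at most one link per ordered pair by
        construction of the mapping.
    """

    def __init__(self, links: Mapping[LinkKey, float]):
        clean: dict[LinkKey, float] = {}
        for (reg, tgt), w in links.items():
            if reg == tgt:
                raise ValueError(f"self-link not allowed: {reg!r}")
            w = float(w)
            if not (0.0 <= w <= 1.0) or math.isnan(w):
                raise ValueError(f"link weight out of [0, 1]: {(reg, tgt, w)}")
            clean[(str(reg), str(tgt))] = w
        self.links: dict[LinkKey, float] = clean

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.links}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.links}

    def regulator_sets(self) -> dict[str, frozenset[str]]:
        """Regulator set per target gene (the R_g used for Jaccard co-regulation)."""
        by_target: dict[str, set[str]] = {}
        for reg, tgt in self.links:
            by_target.setdefault(tgt, set()).add(reg)
        return {t: frozenset(rs) for t, rs in by_target.items()}

    def subset(self, keys: Iterable[LinkKey]) -> "GeneRegulatoryNetwork":
        keys = set(keys)
        return GeneRegulatoryNetwork({k: w for k, w in self.links.items() if k in keys})

    def __len__(self) -> int:
        return len(self.links)

    def __contains__(self, key: LinkKey) -> bool:
        return key in self.links

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneRegulatoryNetwork) and self.links == other.links

    def __repr__(self) -> str:
        return (
            f"GeneRegulatoryNetwork({len(self.links)} links, "
            f"{len(self.regulators)} regulators, {len(self.targets)} targets)"
        )


@dataclass(frozen=True)
class BindingNetwork:
    """DNA-binding prior: an unweighted set of (regulator, target) edges."""

    edges: frozenset[LinkKey]

    @classmethod
    def from_pairs(cls, pairs: Iterable[LinkKey]) -> "BindingNetwork":
        # self-edges carry no information for the intersection step
        return cls(frozenset((r, t) for r, t in pairs if r != t))

    def __contains__(self, key: LinkKey) -> bool:
        return key in self.edges

    def __len__(self) -> int:
        return len(self.edges)


class CoFunctionNetwork:
    """Undirected weighted gene-gene co-functionality network.

    Weights ``w_ff`` lie in [0, 1].  A missing pair means the evidence is
    unknown and is treated as zero coupling (co-function compendia cover only
    part of the genome; absent evidence contributes nothing).
    """

    def __init__(self, pairs: Mapping[frozenset, float] | None = None):
        self.pairs: dict[frozenset, float] = {}
        if pairs:
            for key, w in pairs.items():
                key = frozenset(key)
                if len(key) != 2:
                    raise ValueError(f"co-function pair must join two distinct genes: {set(key)}")
                w = float(w)
                if not (0.0 <= w <= 1.0):
                    raise ValueError(f"co-function weight out of [0, 1]: {w}")
                self.pairs[key] = w

    def weight(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError("co-functionality of a gene with itself is undefined")
        return self.pairs.get(frozenset((a, b)), 0.0)

    def set(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValueError("self-pair not allowed")
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"co-function weight out of [0, 1]: {w}")
        self.pairs[frozenset((a, b))] = float(w)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GoldStandards:
    """Sparse curated positives used for semi-supervised hyperparameter learning.

    ``regulatory_pairs`` drive the precision surface; ``cofunction_pairs``
    (co-annotated gene pairs, e.g. from GO) drive the co-functional recall
    surface.  Both are deduplicated and free of self-pairs.
    """

    regulatory_pairs: frozenset[LinkKey]
    cofunction_pairs: frozenset[frozenset]

    @classmethod
    def build(
        cls,
        regulatory_pairs: Iterable[LinkKey],
        cofunction_pairs: Iterable[Iterable[str]],
    ) -> "GoldStandards":
        reg = frozenset((r, t) for r, t in regulatory_pairs if r != t)
        cof = set()
        for pair in cofunction_pairs:
            fs = frozenset(pair)
            if len(fs) == 2:
                cof.add(fs)
        return cls(reg, frozenset(cof))

    @property
    def gold_regulators(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.regulatory_pairs)


class Hyperparameters(NamedTuple):
    """The learned pair theta = (gamma, lambda).

    gamma is the link-weight threshold: an isolated link with weight <= gamma
    is removed.  lam (lambda) scales the pairwise co-regulation coupling; it
    must be positive.
    """

    gamma: float
    lam: float

    def validate(self) -> "Hyperparameters":
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        return self


class MetaEdge(NamedTuple):
    """Coupling between two links sharing a regulator, weighted by v_delta in [0, 1]."""

    link_a: LinkKey
    link_b: LinkKey
    weight: float


@dataclass(frozen=True)
class MetaModule:
    """A per-regulator group of links reduced to a maximum spanning tree.

    ``nodes`` are the member link keys, ``weights`` their confidence weights,
    and ``tree_edges`` the retained spanning-tree couplings (empty for a
    single-link module).  Invariant: ``len(tree_edges) == len(nodes) - 1``.
    """

    module_id: int
    regulator: str
    nodes: tuple[LinkKey, ...]
    weights: dict[LinkKey, float] = field(hash=False)
    tree_edges: tuple[MetaEdge, ...] = ()

    def __post_init__(self):
        if len(self.tree_edges) != len(self.nodes) - 1:
            raise ValueError(
                f"module {self.module_id}: {len(self.nodes)} nodes need "
                f"{len(self.nodes) - 1} tree edges, got {len(self.tree_edges)}"
            )
        node_set = set(self.nodes)
        for e in self.tree_edges:
            if e.link_a not in node_set or e.link_b not in node_set:
                raise ValueError(f"tree edge {e} references a link outside the module")

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)
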