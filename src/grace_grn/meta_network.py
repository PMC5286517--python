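"""Meta gene regulatory network: links become nodes, shared regulators connect them.

Two links ``r -> g`` and ``r -> g'`` (same regulator, distinct targets) are
joined by a meta edge whose weight combines the genes' co-functionality
``w_ff`` with the similarity of the two link weights:

    v_delta = w_ff * (1 - |v_a - v_b|)        (default rule)

so coupling grows with co-functional evidence and shrinks as the link
weights diverge.  An alternative rule ``w_ff / (1 + |v_a - v_b|)`` is
available via ``combination="inverse_distance"``.

Each per-regulator connected component is reduced to its maximum spanning
tree (maximizing total v_delta), which removes loops so exact inference is
possible downstream; isolated links become single-link modules.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .datatypes import (
    CoFunctionNetwork,
    GeneRegulatoryNetwork,
    LinkKey,
    MetaEdge,
    MetaModule,
)

__all__ = [
    "pairwise_distance",
    "meta_edge_weight",
    "build_meta_network",
    "extract_modules",
    "build_modules",
]


def pairwise_distance(v_a: float, v_b: float) -> float:
    """Absolute distance between two link weights, in [0, 1]."""
    for v in (v_a, v_b):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"link weight out of [0, 1]: {v}")
    return abs(v_a - v_b)


def meta_edge_weight(
    v_a: float,
    v_b: float,
    w_ff: float,
    combination: str = "product",
) -> float:
    """Coupling weight v_delta between two links sharing a regulator."""
    if not (0.0 <= w_ff <= 1.0):
        raise ValueError(f"co-function weight out of [0, 1]: {w_ff}")
    delta = pairwise_distance(v_a, v_b)
    if combination == "product":
        return w_ff * (1.0 - delta)
    if combination == "inverse_distance":
        return w_ff / (1.0 + delta)
    raise ValueError(f"unknown combination rule: {combination!r}")


def build_meta_network(
    grn: GeneRegulatoryNetwork,
    cofn: CoFunctionNetwork,
    combination: str = "product",
) -> list[MetaEdge]:
    """One meta edge per unordered pair of links sharing a regulator.

    Pairs whose co-functionality is unknown get weight 0 (they may still be
    needed by the spanning tree to keep a component connected).
    """
    by_regulator: dict[str, list[LinkKey]] = {}
    for key in grn.links:
        by_regulator.setdefault(key[0], []).append(key)
    edges: list[MetaEdge] = []
    for reg in sorted(by_regulator):
        links = sorted(by_regulator[reg], key=lambda k: k[1])
        for i in range(len(links)):
            for j in range(i + 1, len(links)):
                la, lb = links[i], links[j]
                w_ff = cofn.weight(la[1], lb[1])
                w = meta_edge_weight(grn.links[la], grn.links[lb], w_ff, combination)
                edges.append(MetaEdge(la, lb, w))
    return edges


class _UnionFind:
    def __init__(self, items: Iterable[LinkKey]):
        self.parent = {x: x for x in items}

    def find(self, x: LinkKey) -> LinkKey:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: LinkKey, b: LinkKey) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _maximum_spanning_forest(edges: Sequence[MetaEdge], nodes: Iterable[LinkKey]) -> list[MetaEdge]:
    """Kruskal with a deterministic tie-break.

    Among equal-weight edges the lexicographically smaller
    (regulator, target_a, target_b) triple wins, so results are identical
    across runs and platforms regardless of input order.
    """
    uf = _UnionFind(nodes)
    ordered = sorted(
        edges,
        key=lambda e: (-e.weight, e.link_a[0], e.link_a[1], e.link_b[1]),
    )
    kept = []
    for e in ordered:
        if uf.union(e.link_a, e.link_b):
            kept.append(e)
    return kept


def extract_modules(
    meta_edges: Sequence[MetaEdge],
    grn: GeneRegulatoryNetwork,
) -> list[MetaModule]:
    """Partition all links into spanning-tree modules.

    Every connected component of the meta graph becomes one module carrying
    its maximum spanning tree; links touching no meta edge become single-link
    modules.  Each input link appears in exactly one module.  Because meta
    edges only ever join links with the same regulator, every module is
    per-regulator by construction.
    """
    adjacency: dict[LinkKey, list[MetaEdge]] = {k: [] for k in grn.links}
    for e in meta_edges:
        for end in (e.link_a, e.link_b):
            if end not in adjacency:
                raise ValueError(f"meta edge references link outside the network: {end}")
        adjacency[e.link_a].append(e)
        adjacency[e.link_b].append(e)

    seen: set[LinkKey] = set()
    modules: list[MetaModule] = []
    for start in sorted(grn.links):
        if start in seen:
            continue
        # BFS over the component
        component = [start]
        seen.add(start)
        frontier = [start]
        comp_edges: list[MetaEdge] = []
        while frontier:
            node = frontier.pop()
            for e in adjacency[node]:
                comp_edges.append(e)
                other = e.link_b if e.link_a == node else e.link_a
                if other not in seen:
                    seen.add(other)
                    component.append(other)
                    frontier.append(other)
        component.sort()
        # each undirected edge was collected from both endpoints
        uniq = {(e.link_a, e.link_b): e for e in comp_edges}
        tree = _maximum_spanning_forest(list(uniq.values()), component)
        modules.append(
            MetaModule(
                module_id=len(modules),
                regulator=start[0],
                nodes=tuple(component),
                weights={k: grn.links[k] for k in component},
                tree_edges=tuple(tree),
            )
        )
    return modules


def build_modules(
    grn: GeneRegulatoryNetwork,
    cofn: CoFunctionNetwork,
    combination: str = "product",
) -> list[MetaModule]:
    """Convenience: meta network construction followed by module extraction."""
    return extract_modules(build_meta_network(grn, cofn, combination), grn)
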