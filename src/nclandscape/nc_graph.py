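"""Neutral-component (NC) decomposition and the NC graph.

A neutral component is a maximal set of genotypes that share a phenotype
and are mutually reachable through single phenotype-preserving allowed
substitutions.  The NC graph coarse-grains the genotype space: each NC is
a node annotated with its phenotype, its size |NC| (genotype count) and
its evolvability eps (number of distinct non-deleterious phenotypes among
its mutational neighbors); an undirected edge joins two NCs whenever some
allowed point mutation connects genotypes of the two.

Deleterious genotypes carry fitness zero downstream, play no role in
accessible paths, and are excluded from the decomposition and the graph.
Evolvability therefore counts only non-deleterious neighbor phenotypes:
these are exactly the competitors in a random fitness ranking (an
``include_deleterious`` flag on :func:`compute_evolvabilities` is provided
for sensitivity checks, but nothing in the pipeline uses it).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gp_maps import GPMap, enumerate_genotypes, mutational_neighbors

__all__ = [
    "NCLabeling",
    "NCGraph",
    "decompose_into_ncs",
    "build_nc_graph",
    "compute_evolvabilities",
    "merge_ncs_by_phenotype",
    "geometric_mean_evolvability",
    "summarize_nc_graph",
    "read_nc_graph",
    "write_nc_graph",
    "NCGraphTableError",
]


class NCGraphTableError(ValueError):
    """Raised on inconsistent serialized NC-graph tables."""


@dataclass
class NCLabeling:
    """Partition of the non-deleterious genotypes into neutral components.

    ``nc_id_of`` maps each non-deleterious genotype to an integer NC id;
    ids are assigned in order of first-visited genotype under lexicographic
    enumeration, so labelings are deterministic for a given GP map.
    """

    nc_id_of: dict[str, int]
    phenotype_of_nc: dict[int, str]

    @property
    def n_ncs(self) -> int:
        return len(self.phenotype_of_nc)

    def genotypes_of_nc(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {nc: [] for nc in self.phenotype_of_nc}
        for g, nc in self.nc_id_of.items():
            out[nc].append(g)
        return out

    def sizes(self) -> dict[int, int]:
        counts: dict[int, int] = {nc: 0 for nc in self.phenotype_of_nc}
        for nc in self.nc_id_of.values():
            counts[nc] += 1
        return counts


@dataclass
class NCGraph:
    """Coarse-grained landscape skeleton.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are NC
    ids with attributes ``phenotype`` and ``size``.  ``total_genotypes`` is
    K**L for graphs derived from a GP map (used to normalize ruggedness);
    for synthetic graphs it defaults to the summed NC sizes.
    """

    graph: nx.Graph
    total_genotypes: int
    K: int | None = None
    L: int | None = None
    _evolvability: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._evolvability:
            self._evolvability = compute_evolvabilities(self.graph)

    @property
    def n_ncs(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nc_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def phenotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for nc in self.nc_ids:
            seen.setdefault(self.graph.nodes[nc]["phenotype"], None)
        return list(seen)

    @property
    def n_phenotypes(self) -> int:
        return len({d["phenotype"] for _, d in self.graph.nodes(data=True)})

    @property
    def n_nondeleterious(self) -> int:
        return int(sum(d["size"] for _, d in self.graph.nodes(data=True)))

    def phenotype(self, nc_id: int) -> str:
        return self.graph.nodes[nc_id]["phenotype"]

    def size(self, nc_id: int) -> int:
        return self.graph.nodes[nc_id]["size"]

    def evolvability(self, nc_id: int) -> int:
        return self._evolvability[nc_id]

    def evolvabilities(self) -> dict[int, int]:
        return dict(self._evolvability)

    def sizes(self) -> dict[int, int]:
        return {nc: self.graph.nodes[nc]["size"] for nc in self.graph.nodes}


def decompose_into_ncs(gp_map: GPMap, size_cap: int = 10**8) -> NCLabeling:
    """Label every non-deleterious genotype with its neutral component.

    Breadth-first flood fill over the allowed-mutation graph restricted to
    equal phenotypes; working memory is one label per genotype.
    """
    nc_id_of: dict[str, int] = {}
    phenotype_of_nc: dict[int, str] = {}
    deleterious = gp_map.deleterious_label
    next_id = 0
    for genotype in enumerate_genotypes(gp_map, size_cap=size_cap):
        if genotype in nc_id_of:
            continue
        phenotype = gp_map.phenotype_of(genotype)
        if phenotype == deleterious:
            continue
        nc = next_id
        next_id += 1
        phenotype_of_nc[nc] = phenotype
        nc_id_of[genotype] = nc
        queue = deque([genotype])
        while queue:
            g = queue.popleft()
            for h in mutational_neighbors(g, gp_map):
                if h in nc_id_of:
                    continue
                if gp_map.phenotype_of(h) == phenotype:
                    nc_id_of[h] = nc
                    queue.append(h)
    return NCLabeling(nc_id_of=nc_id_of, phenotype_of_nc=phenotype_of_nc)


def build_nc_graph(
    gp_map: GPMap,
    labeling: NCLabeling,
    include_deleterious_in_evolvability: bool = False,
) -> NCGraph:
    """Scan all mutations of all genotypes and assemble the NC graph.

    By default evolvability counts only non-deleterious neighbor phenotypes
    (a fitness-zero neighbor can never outrank a positive-fitness NC in a
    random ranking).  The ``include_deleterious_in_evolvability`` flag adds
    one to the evolvability of every NC that borders the deleterious class,
    for sensitivity analyses only.
    """
    sizes = labeling.sizes()
    g = nx.Graph()
    for nc, phenotype in labeling.phenotype_of_nc.items():
        g.add_node(nc, phenotype=phenotype, size=sizes[nc])
    touches_deleterious: set[int] = set()
    for genotype, nc in labeling.nc_id_of.items():
        for h in mutational_neighbors(genotype, gp_map):
            other = labeling.nc_id_of.get(h)
            if other is None:
                touches_deleterious.add(nc)
                continue
            if other == nc:
                continue
            if labeling.phenotype_of_nc[other] == labeling.phenotype_of_nc[nc]:
                raise ValueError(
                    "labeling is not maximal: same-phenotype NCs "
                    f"{nc} and {other} are mutationally connected"
                )
            g.add_edge(nc, other)
    eps = compute_evolvabilities(g)
    if include_deleterious_in_evolvability:
        for nc in touches_deleterious:
            eps[nc] += 1
    return NCGraph(
        graph=g,
        total_genotypes=gp_map.n_genotypes,
        K=gp_map.K,
        L=gp_map.L,
        _evolvability=eps,
    )


def compute_evolvabilities(graph: nx.Graph) -> dict[int, int]:
    """Distinct neighbor phenotypes per node.

    Deleterious genotypes never appear as NC-graph nodes, so this is the
    count of distinct phenotypes among each node's graph neighbors; it can
    be smaller than the degree when two neighboring NCs share a phenotype.
    """
    eps: dict[int, int] = {}
    for nc in graph.nodes:
        phenos = {graph.nodes[m]["phenotype"] for m in graph.neighbors(nc)}
        eps[nc] = len(phenos)
    return eps


def merge_ncs_by_phenotype(nc_graph: NCGraph) -> NCGraph:
    """Collapse all NCs of each phenotype into a single node.

    Models the "more connected" variant of a landscape in which all neutral
    components of a phenotype are joined by additional mutational links.
    Sizes add; an edge joins two phenotypes iff any constituent NC pair was
    adjacent.  Idempotent.
    """
    g = nc_graph.graph
    # Deterministic new ids: order of the smallest constituent NC id.
    first_member: dict[str, int] = {}
    for nc in sorted(g.nodes):
        first_member.setdefault(g.nodes[nc]["phenotype"], nc)
    order = sorted(first_member, key=lambda p: first_member[p])
    new_id = {p: i for i, p in enumerate(order)}
    merged = nx.Graph()
    for p in order:
        merged.add_node(new_id[p], phenotype=p, size=0)
    for nc, d in g.nodes(data=True):
        merged.nodes[new_id[d["phenotype"]]]["size"] += d["size"]
    for a, b in g.edges:
        pa, pb = g.nodes[a]["phenotype"], g.nodes[b]["phenotype"]
        if pa != pb:
            merged.add_edge(new_id[pa], new_id[pb])
    return NCGraph(
        graph=merged, total_genotypes=nc_graph.total_genotypes, K=nc_graph.K, L=nc_graph.L
    )


def geometric_mean_evolvability(nc_graph: NCGraph, zero_replacement: float = 0.01) -> float:
    """Geometric mean of NC evolvabilities, with zeros replaced.

    A single eps = 0 node would force the geometric mean to zero, so zero
    values are replaced by ``zero_replacement`` (default 0.01).
    """
    if nc_graph.n_ncs == 0:
        raise ValueError("empty NC graph")
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    eps = np.array([nc_graph.evolvability(nc) for nc in nc_graph.nc_ids], dtype=float)
    eps[eps == 0] = zero_replacement
    return float(np.exp(np.mean(np.log(eps))))


def summarize_nc_graph(nc_graph: NCGraph) -> dict:
    """Summary statistics: counts, size / evolvability distributions, and
    the rank correlation between NC size and evolvability."""
    if nc_graph.n_ncs == 0:
        raise ValueError("empty NC graph")
    ids = nc_graph.nc_ids
    sizes = np.array([nc_graph.size(nc) for nc in ids])
    eps = np.array([nc_graph.evolvability(nc) for nc in ids])
    if len(ids) > 1 and len(set(sizes)) > 1 and len(set(eps)) > 1:
        rho = float(stats.spearmanr(sizes, eps).statistic)
    else:
        rho = float("nan")
    mean_size_by_eps = {
        int(e): float(sizes[eps == e].mean()) for e in np.unique(eps)
    }
    return {
        "n_ncs": nc_graph.n_ncs,
        "n_edges": nc_graph.n_edges,
        "n_phenotypes": nc_graph.n_phenotypes,
        "n_nondeleterious_genotypes": nc_graph.n_nondeleterious,
        "total_genotypes": nc_graph.total_genotypes,
        "size_distribution": {int(s): int((sizes == s).sum()) for s in np.unique(sizes)},
        "evolvability_distribution": {int(e): int((eps == e).sum()) for e in np.unique(eps)},
        "mean_evolvability": float(eps.mean()),
        "geometric_mean_evolvability": geometric_mean_evolvability(nc_graph),
        "size_evolvability_rank_correlation": rho,
        "mean_size_by_evolvability": mean_size_by_eps,
    }


def write_nc_graph(nc_graph: NCGraph, node_path: str | Path, edge_path: str | Path) -> None:
    """Write node and edge tables as TSV."""
    ids = nc_graph.nc_ids
    nodes = pd.DataFrame(
        {
            "nc_id": ids,
            "phenotype": [nc_graph.phenotype(nc) for nc in ids],
            "size": [nc_graph.size(nc) for nc in ids],
            "evolvability": [nc_graph.evolvability(nc) for nc in ids],
        }
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in nc_graph.graph.edges),
        columns=["nc_id_1", "nc_id_2"],
    )
    edges.to_csv(edge_path, sep="\t", index=False)


def read_nc_graph(
    node_path: str | Path,
    edge_path: str | Path,
    total_genotypes: int | None = None,
    K: int | None = None,
    L: int | None = None,
) -> NCGraph:
    """Read node/edge TSVs; recompute evolvability and verify the stored column."""
    nodes = pd.read_csv(node_path, sep="\t", dtype={"phenotype": str}, keep_default_na=False)
    edges = pd.read_csv(edge_path, sep="\t")
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(int(row.nc_id), phenotype=str(row.phenotype), size=int(row.size))
    known = set(g.nodes)
    for row in edges.itertuples(index=False):
        a, b = int(row.nc_id_1), int(row.nc_id_2)
        for end in (a, b):
            if end not in known:
                raise NCGraphTableError(f"edge ({a}, {b}) references unknown NC id {end}")
        g.add_edge(a, b)
    eps = compute_evolvabilities(g)
    for row in nodes.itertuples(index=False):
        stored = int(row.evolvability)
        if stored != eps[int(row.nc_id)]:
            raise NCGraphTableError(
                f"stored evolvability {stored} of NC {int(row.nc_id)} is inconsistent "
                f"with the edge table (recomputed {eps[int(row.nc_id)]})"
            )
    if total_genotypes is None:
        total_genotypes = int(nodes["size"].sum()) if K is None or L is None else K**L
    return NCGraph(graph=g, total_genotypes=total_genotypes, K=K, L=L)
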