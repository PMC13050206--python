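"""Registry of small named test landscapes with oracle-derived expectations.

Each fixture is generated programmatically — toy GP maps (Fibonacci family,
degenerate single-phenotype and all-distinct maps, a shared-neighbor-
phenotype construction) or a hand-built NC graph (the fitness valley).  The
expected NC counts, size multisets and evolvabilities attached to each GP
map are computed at build time by the independent genotype-level oracle,
not by the pipeline under test.
"""

from __future__ import annotations

import itertools
from typing import Any

import networkx as nx

from .gp_maps import (
    FibonacciGPMap,
    GPMap,
    LowEvolvabilityFibonacciGPMap,
    TabularGPMap,
)
from .nc_graph import NCGraph
from .oracles import _all_genotypes, _allowed_neighbors, brute_force_ncs

__all__ = ["FIXTURE_NAMES", "generate_fixture"]


def _oracle_expectations(gp_map: GPMap) -> dict[str, Any]:
    """NC counts, sizes and evolvabilities derived purely from the oracle."""
    labeling = brute_force_ncs(gp_map)
    phenotype = {g: gp_map.phenotype_of(g) for g in _all_genotypes(gp_map)}
    eps: dict[int, int] = {}
    for nc, genotypes in labeling.genotypes_of_nc().items():
        own = labeling.phenotype_of_nc[nc]
        neighbor_phenos = {
            phenotype[h]
            for g in genotypes
            for h in _allowed_neighbors(g, gp_map)
        }
        neighbor_phenos.discard(own)
        neighbor_phenos.discard(gp_map.deleterious_label)
        eps[nc] = len(neighbor_phenos)
    sizes = labeling.sizes()
    return {
        "n_ncs": labeling.n_ncs,
        "sizes": {nc: sizes[nc] for nc in sorted(sizes)},
        "size_multiset": sorted(sizes.values()),
        "evolvability": {nc: eps[nc] for nc in sorted(eps)},
        "phenotype_of_nc": dict(labeling.phenotype_of_nc),
    }


def _single_phenotype_map(K: int, L: int) -> TabularGPMap:
    alphabet = tuple("01234"[:K])
    table = {"".join(t): "A" for t in itertools.product(alphabet, repeat=L)}
    return TabularGPMap.from_dict(table, alphabet=alphabet)


def _all_distinct_map(K: int, L: int) -> TabularGPMap:
    alphabet = tuple("01234"[:K])
    table = {
        "".join(t): f"p{i}"
        for i, t in enumerate(itertools.product(alphabet, repeat=L))
    }
    return TabularGPMap.from_dict(table, alphabet=alphabet)


def _shared_neighbor_phenotype_map() -> TabularGPMap:
    # Phenotype B splits into two NCs ({0001} and {0010}, Hamming distance 2)
    # that both touch the single NC of phenotype A ({0000}): the A node has
    # degree 2 on the NC graph but evolvability 1.
    table = {}
    for t in itertools.product("01", repeat=4):
        g = "".join(t)
        table[g] = "DELETERIOUS"
    table["0000"] = "A"
    table["0001"] = "B"
    table["0010"] = "B"
    return TabularGPMap.from_dict(table, alphabet=("0", "1"))


def _valley_nc_graph() -> NCGraph:
    # Path A - B - C - D of single-NC phenotypes; with a user PF map making
    # B a sub-optimal peak and D the optimum, the valley at C separates A
    # from D.
    g = nx.Graph()
    for i, p in enumerate("ABCD"):
        g.add_node(i, phenotype=p, size=1)
    g.add_edges_from([(0, 1), (1, 2), (2, 3)])
    return NCGraph(graph=g, total_genotypes=4)


FIXTURE_NAMES = (
    "fibonacci_L3",
    "fibonacci_L4",
    "fibonacci_L5",
    "le_fibonacci_L4",
    "single_phenotype_K2_L3",
    "all_distinct_K2_L2",
    "shared_neighbor_phenotype_K2_L4",
    "valley_digraph",
)


def generate_fixture(name: str) -> tuple[Any, dict[str, Any]]:
    """Return ``(object, expected)`` for a registered fixture name.

    The object is a GP map for genotype-level fixtures or an NC graph for
    the valley digraph; ``expected`` carries oracle-computed reference
    values (empty for the hand-built graph, whose structure is its own
    specification).
    """
    if name == "fibonacci_L3":
        m = FibonacciGPMap(length=3)
    elif name == "fibonacci_L4":
        m = FibonacciGPMap(length=4)
    elif name == "fibonacci_L5":
        m = FibonacciGPMap(length=5)
    elif name == "le_fibonacci_L4":
        m = LowEvolvabilityFibonacciGPMap(length=4)
    elif name == "single_phenotype_K2_L3":
        m = _single_phenotype_map(2, 3)
    elif name == "all_distinct_K2_L2":
        m = _all_distinct_map(2, 2)
    elif name == "shared_neighbor_phenotype_K2_L4":
        m = _shared_neighbor_phenotype_map()
    elif name == "valley_digraph":
        return _valley_nc_graph(), {"n_ncs": 4, "edges": [(0, 1), (1, 2), (2, 3)]}
    else:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return m, _oracle_expectations(m)
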