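"""Independent genotype-level brute-force oracles.

These implementations deliberately share no graph code with the main
pipeline — only the GP-map contract (``phenotype_of``, ``mutation_allowed``,
alphabet, length).  Genotype enumeration and neighborhoods are re-derived
inline, components are found by union-find rather than breadth-first flood
fill, and peaks and accessibility are decided directly on the genotype
Hamming graph.  They exist to validate the NC-level pipeline exactly on
small instances, never to stand in for it.
"""

from __future__ import annotations

import itertools
from math import factorial

from .gp_maps import GPMap
from .nc_graph import NCGraph, NCLabeling
from .pf_maps import PFMap

__all__ = [
    "brute_force_ncs",
    "brute_force_peaks",
    "brute_force_accessible",
    "exhaustive_ranking_peak_fractions",
    "OracleSizeError",
]

DEFAULT_ORACLE_CAP = 4096


class OracleSizeError(ValueError):
    """Instance too large for exhaustive brute force."""


def _check_cap(gp_map: GPMap, cap: int) -> None:
    if gp_map.n_genotypes > cap:
        raise OracleSizeError(
            f"K^L = {gp_map.n_genotypes} exceeds the oracle cap of {cap}"
        )


def _all_genotypes(gp_map: GPMap) -> list[str]:
    return ["".join(t) for t in itertools.product(gp_map.alphabet, repeat=gp_map.length)]


def _allowed_neighbors(g: str, gp_map: GPMap) -> list[str]:
    out = []
    for pos in range(len(g)):
        for letter in gp_map.alphabet:
            if letter != g[pos] and gp_map.mutation_allowed(g, pos, letter):
                out.append(g[:pos] + letter + g[pos + 1 :])
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def brute_force_ncs(gp_map: GPMap, cap: int = DEFAULT_ORACLE_CAP) -> NCLabeling:
    """Union-find component labeling of the phenotype-preserving mutation graph.

    NC ids are assigned by the lexicographic rank of each component's
    smallest genotype, matching the deterministic id convention of the main
    decomposition without sharing its traversal code.
    """
    _check_cap(gp_map, cap)
    phenotype = {g: gp_map.phenotype_of(g) for g in _all_genotypes(gp_map)}
    nondel = [g for g, p in phenotype.items() if p != gp_map.deleterious_label]
    uf = _UnionFind(nondel)
    nondel_set = set(nondel)
    for g in nondel:
        for h in _allowed_neighbors(g, gp_map):
            if h in nondel_set and phenotype[h] == phenotype[g]:
                uf.union(g, h)
    members: dict[str, list[str]] = {}
    for g in nondel:
        members.setdefault(uf.find(g), []).append(g)
    components = sorted(members.values(), key=min)
    nc_id_of = {g: i for i, comp in enumerate(components) for g in comp}
    phenotype_of_nc = {i: phenotype[comp[0]] for i, comp in enumerate(components)}
    return NCLabeling(nc_id_of=nc_id_of, phenotype_of_nc=phenotype_of_nc)


def brute_force_peaks(
    gp_map: GPMap, pf_map: PFMap, cap: int = DEFAULT_ORACLE_CAP
) -> set[frozenset[str]]:
    """Peak NCs found without any NC graph, as frozensets of genotypes.

    An NC is a peak iff no genotype in it has a strictly fitter allowed
    mutational neighbor (neighbors inside the NC share its fitness).
    """
    labeling = brute_force_ncs(gp_map, cap=cap)
    fitness = {
        g: pf_map.fitness(gp_map.phenotype_of(g)) for g in labeling.nc_id_of
    }
    peaks: set[frozenset[str]] = set()
    for nc, genotypes in labeling.genotypes_of_nc().items():
        member_set = set(genotypes)
        is_peak = True
        for g in genotypes:
            for h in _allowed_neighbors(g, gp_map):
                if h in member_set:
                    continue
                if fitness.get(h, 0.0) >= fitness[g]:
                    is_peak = False
                    break
            if not is_peak:
                break
        if is_peak:
            peaks.add(frozenset(member_set))
    return peaks


def brute_force_accessible(
    gp_map: GPMap,
    pf_map: PFMap,
    start: str,
    target_phenotype: str,
    cap: int = DEFAULT_ORACLE_CAP,
) -> bool:
    """Genotype-space search for a fitness-non-decreasing mutational path
    from ``start`` to any genotype of ``target_phenotype``.

    Deleterious genotypes are never entered.  Because steps only require
    fitness(next) >= fitness(current), reachability is transitive and plain
    graph search over visited genotypes is exact.
    """
    _check_cap(gp_map, cap)
    if gp_map.phenotype_of(start) == gp_map.deleterious_label:
        raise ValueError(f"start genotype {start!r} is deleterious")
    fitness_of = lambda g: pf_map.fitness(gp_map.phenotype_of(g))  # noqa: E731
    seen = {start}
    stack = [start]
    while stack:
        g = stack.pop()
        if gp_map.phenotype_of(g) == target_phenotype:
            return True
        fg = fitness_of(g)
        for h in _allowed_neighbors(g, gp_map):
            if h in seen or gp_map.phenotype_of(h) == gp_map.deleterious_label:
                continue
            if fitness_of(h) >= fg:
                seen.add(h)
                stack.append(h)
    return False


def exhaustive_ranking_peak_fractions(
    nc_graph: NCGraph, max_phenotypes: int = 8
) -> dict[int, float]:
    """Fraction of all fitness rankings in which each NC is a peak.

    Enumerates every permutation of the graph's phenotypes as a fitness
    ranking and checks strict superiority over all neighbors.  When an NC's
    neighbor phenotypes are all distinct competitors this fraction equals
    1/(eps + 1) exactly.
    """
    phenotypes = nc_graph.phenotypes
    n = len(phenotypes)
    if n > max_phenotypes:
        raise OracleSizeError(f"{n} phenotypes exceed the permutation cap of {max_phenotypes}")
    counts = {nc: 0 for nc in nc_graph.nc_ids}
    neighbors = {
        nc: list(nc_graph.graph.neighbors(nc)) for nc in nc_graph.nc_ids
    }
    for perm in itertools.permutations(range(n)):
        rank = dict(zip(phenotypes, perm))
        for nc in counts:
            r = rank[nc_graph.phenotype(nc)]
            if all(rank[nc_graph.phenotype(m)] < r for m in neighbors[nc]):
                counts[nc] += 1
    total = factorial(n)
    return {nc: c / total for nc, c in counts.items()}
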