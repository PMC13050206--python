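"""Navigability: accessible paths to the global optimum on NC graphs.

Orienting every NC-graph edge toward its fitter endpoint turns a tie-free
realization into a DAG in which directed paths are exactly the accessible
(fitness-non-decreasing) paths of the underlying landscape.  Navigability
is the probability, over random PF maps and random source phenotypes, that
a directed path exists from a size-weighted random start NC of the source
phenotype to any NC of the highest-fitness phenotype.

For the idealized case of one NC per phenotype with constant connection
probability eps_bar/(n_p - 1) per pair, the expected number of accessible
paths scales such that navigability stays below delta whenever

    eps_bar <~ n_p * ((delta * n_p)^(1/n_p) - 1),

which approaches ln(delta * n_p) for large n_p.  The bound marks a
low-evolvability regime of non-navigable maps; it is one-sided and says
nothing about high-evolvability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .nc_graph import NCGraph
from .pf_maps import DistributionSpec, LandscapeRealization, attach_fitness, draw_pf_map

__all__ = [
    "NavigabilityEstimate",
    "orient_uphill",
    "accessible_path_exists",
    "estimate_navigability",
    "evolvability_bound",
    "synthetic_constant_evolvability_graph",
]


@dataclass
class NavigabilityEstimate:
    """Success fraction of accessibility trials, with per-trial records."""

    n_pf_maps: int
    n_sources: int
    n_success: int
    navigability: float
    trials: list[dict] = field(default_factory=list)
    source_policy: str = "uniform-with-replacement; source == target counts as success"


def orient_uphill(realization: LandscapeRealization) -> nx.DiGraph:
    """Directed version of the NC graph with arcs pointing uphill.

    Strict fitness ordering makes the result acyclic.
    """
    fit = realization.node_fitness
    dg = nx.DiGraph()
    dg.add_nodes_from(realization.nc_graph.graph.nodes(data=True))
    for a, b in realization.nc_graph.graph.edges:
        if fit[a] == fit[b]:
            raise ValueError(f"fitness tie on edge ({a}, {b}); realization is invalid")
        if fit[a] < fit[b]:
            dg.add_edge(a, b)
        else:
            dg.add_edge(b, a)
    return dg


def accessible_path_exists(
    directed: nx.DiGraph, start_nc: int, target_phenotype: str
) -> bool:
    """Whether a directed (fitness-increasing) path reaches any NC of the
    target phenotype; a start already of the target phenotype counts via
    the length-0 path."""
    if start_nc not in directed:
        raise KeyError(f"unknown start NC {start_nc}")
    targets = {n for n, d in directed.nodes(data=True) if d["phenotype"] == target_phenotype}
    if not targets:
        raise KeyError(f"no NC of phenotype {target_phenotype!r} in the graph")
    if start_nc in targets:
        return True
    reachable = {start_nc} | nx.descendants(directed, start_nc)
    return bool(reachable & targets)


def _reverse_reachable(directed: nx.DiGraph, targets: set[int]) -> set[int]:
    """All nodes with a directed path into ``targets`` (including them)."""
    seen = set(targets)
    stack = list(targets)
    while stack:
        node = stack.pop()
        for pred in directed.predecessors(node):
            if pred not in seen:
                seen.add(pred)
                stack.append(pred)
    return seen


def estimate_navigability(
    nc_graph: NCGraph,
    distribution: DistributionSpec,
    n_pf_maps: int = 500,
    n_sources: int = 10,
    seed: int = 0,
    deleterious_label: str = "DELETERIOUS",
    exclude_target_source: bool = False,
    keep_trials: bool = False,
) -> NavigabilityEstimate:
    """Monte Carlo navigability over PF maps and source phenotypes.

    Per PF map the target is the highest-fitness phenotype; each of
    ``n_sources`` source phenotypes is drawn uniformly with replacement,
    its start NC size-weighted among that phenotype's NCs, and one
    reachability test is run.  Reachability is computed once per PF map by
    reverse search from all target NCs, which by construction answers every
    per-source forward query.  A source equal to the target succeeds via
    the length-0 path unless ``exclude_target_source`` redraws it.
    """
    if nc_graph.n_ncs == 0:
        raise ValueError("empty NC graph")
    phenotypes = nc_graph.phenotypes
    ncs_of_phenotype: dict[str, list[int]] = {}
    for nc in nc_graph.nc_ids:
        ncs_of_phenotype.setdefault(nc_graph.phenotype(nc), []).append(nc)
    n_success = 0
    trials: list[dict] = []
    for i in range(n_pf_maps):
        rng = np.random.default_rng((seed, i))
        pf = draw_pf_map(
            phenotypes + [deleterious_label], distribution, rng, deleterious_label
        )
        realization = attach_fitness(nc_graph, pf)
        directed = orient_uphill(realization)
        target = max(phenotypes, key=pf.fitness)
        reach = _reverse_reachable(directed, set(ncs_of_phenotype[target]))
        for _ in range(n_sources):
            while True:
                source = phenotypes[rng.integers(len(phenotypes))]
                if not (exclude_target_source and source == target):
                    break
            members = ncs_of_phenotype[source]
            sizes = np.array([nc_graph.size(nc) for nc in members], dtype=float)
            start = members[rng.choice(len(members), p=sizes / sizes.sum())]
            success = start in reach
            n_success += success
            if keep_trials:
                trials.append(
                    {
                        "pf_index": i,
                        "source_phenotype": source,
                        "start_nc": start,
                        "target_phenotype": target,
                        "success": bool(success),
                    }
                )
    total = n_pf_maps * n_sources
    return NavigabilityEstimate(
        n_pf_maps=n_pf_maps,
        n_sources=n_sources,
        n_success=n_success,
        navigability=n_success / total if total else float("nan"),
        trials=trials,
    )


def evolvability_bound(n_p: int, delta: float) -> float:
    """Mean evolvability below which a constant-evolvability NC graph is
    expected to have navigability under ``delta``:

        n_p * ((delta * n_p)^(1/n_p) - 1)

    May be non-positive for small n_p (vacuous bound); approaches
    ln(delta * n_p) as n_p grows.
    """
    if n_p < 2:
        raise ValueError(f"n_p must be >= 2, got {n_p}")
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    return float(n_p * ((delta * n_p) ** (1.0 / n_p) - 1.0))


def synthetic_constant_evolvability_graph(
    n_p: int, mean_evolvability: float, seed: int = 0
) -> NCGraph:
    """Random NC graph with one unit-size NC per phenotype and i.i.d. edges.

    Each unordered pair is connected independently with probability
    eps_bar/(n_p - 1), so the expected evolvability of every node equals
    ``mean_evolvability``.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    if not 0 <= mean_evolvability <= n_p - 1:
        raise ValueError(
            f"mean evolvability must lie in [0, n_p - 1] = [0, {n_p - 1}], got {mean_evolvability}"
        )
    p = mean_evolvability / (n_p - 1) if n_p > 1 else 0.0
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    for i in range(n_p):
        g.add_node(i, phenotype=f"p{i}", size=1)
    if p > 0:
        iu, ju = np.triu_indices(n_p, k=1)
        mask = rng.random(len(iu)) < p
        g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return NCGraph(graph=g, total_genotypes=n_p)
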