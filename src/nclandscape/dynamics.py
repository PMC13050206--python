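"""Adaptive walks in the strong-selection weak-mutation (SSWM) regime.

The evolving population is approximated by a single walker on the full
genotype space.  From its current genotype the walker lists all mutational
neighbors that are neutral or fitness-increasing (deleterious and downhill
neighbors are excluded), weights each by its Kimura fixation probability at
population size N, and moves to one of them; the walk ends when the current
genotype's neutral component is a peak of the realization.

Walks are run at genotype level rather than NC level so that size effects
(transitions into large NCs being available from more genotypes) can
emerge, as they would in a real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gp_maps import GPMap, enumerate_genotypes, mutational_neighbors
from .nc_graph import NCGraph, NCLabeling, build_nc_graph, decompose_into_ncs
from .pf_maps import DistributionSpec, LandscapeRealization, attach_fitness, draw_pf_map
from .topography import find_peaks

__all__ = [
    "WalkResult",
    "WalkEnsembleResult",
    "WalkEngine",
    "EmptyStartSetError",
    "kimura_fixation_probability",
    "sample_walk_start",
    "adaptive_walk",
    "walk_ensemble",
]

DEFAULT_POPULATION_SIZE = 1000
STEP_CAP = 10**6


class EmptyStartSetError(RuntimeError):
    """No non-peak NC lies below the lowest-fitness peak, so no unbiased
    walk start exists for this realization."""


@dataclass(frozen=True)
class WalkResult:
    start: str
    endpoint: str
    endpoint_nc: int
    endpoint_fitness: float
    n_steps: int
    walker_index: int | None = None
    pf_index: int | None = None


@dataclass
class WalkEnsembleResult:
    """Aggregated endpoints of many walkers across many PF realizations."""

    pf_index: np.ndarray
    endpoint_nc: np.ndarray
    endpoint_fitness: np.ndarray
    n_steps: np.ndarray
    n_pf_maps: int
    n_walkers: int
    n_redrawn_pf_maps: int
    peak_visit_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    peak_ncs_by_map: dict[int, frozenset[int]] = field(default_factory=dict)

    def endpoint_cdf(self, grid: np.ndarray) -> np.ndarray:
        """Pooled empirical CDF of endpoint fitness on a fitness grid."""
        f = np.sort(self.endpoint_fitness)
        return np.searchsorted(f, grid, side="right") / len(f)

    def per_map_endpoint_cdfs(self, grid: np.ndarray) -> np.ndarray:
        """One empirical endpoint-fitness CDF per PF map (rows)."""
        out = np.empty((self.n_pf_maps, len(grid)))
        for i in range(self.n_pf_maps):
            f = np.sort(self.endpoint_fitness[self.pf_index == i])
            out[i] = np.searchsorted(f, grid, side="right") / max(len(f), 1)
        return out


def kimura_fixation_probability(
    f_current, f_candidate, N: int, variant: str = "haploid"
):
    """Fixation probability of a mutant with selection s = f'/f - 1.

    The haploid form (1 - e^(-2s)) / (1 - e^(-2Ns)) is used by default,
    with the continuous neutral limit 1/N at s = 0; the diploid variant
    replaces the denominator exponent by 4Ns (neutral limit 1/(2N)).
    Downstream results depend only on fitness ranks and are robust to the
    variant choice.
    """
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    if variant not in ("haploid", "diploid"):
        raise ValueError(f"unknown variant {variant!r}")
    f_current = np.asarray(f_current, dtype=float)
    f_candidate = np.asarray(f_candidate, dtype=float)
    if np.any(f_current <= 0) or np.any(f_candidate <= 0):
        raise ValueError("fitness values must be positive (walkers never occupy deleterious genotypes)")
    s = f_candidate / f_current - 1.0
    denom_factor = 2 * N if variant == "haploid" else 4 * N
    neutral = 1.0 / N if variant == "haploid" else 1.0 / (2 * N)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.expm1(-2.0 * s) / np.expm1(-denom_factor * s)
    p = np.where(s == 0.0, neutral, p)
    return float(p) if p.ndim == 0 else p


class WalkEngine:
    """Precomputed genotype-level arrays for fast repeated walks.

    Indexes genotypes in lexicographic enumeration order and stores allowed
    neighbor indices, NC membership and per-NC genotype lists once per GP
    map, so that each realization only needs an NC-fitness lookup.
    """

    def __init__(self, gp_map: GPMap, labeling: NCLabeling | None = None):
        self.gp_map = gp_map
        self.labeling = labeling if labeling is not None else decompose_into_ncs(gp_map)
        self.genotypes = list(enumerate_genotypes(gp_map))
        self.index = {g: i for i, g in enumerate(self.genotypes)}
        n = len(self.genotypes)
        self.neighbors = [
            np.array([self.index[h] for h in mutational_neighbors(g, gp_map)], dtype=np.int64)
            for g in self.genotypes
        ]
        self.nc_of = np.full(n, -1, dtype=np.int64)
        for g, nc in self.labeling.nc_id_of.items():
            self.nc_of[self.index[g]] = nc
        self.genotype_indices_of_nc = {
            nc: np.array(sorted(self.index[g] for g in gs), dtype=np.int64)
            for nc, gs in self.labeling.genotypes_of_nc().items()
        }

    def nc_fitness_array(self, realization: LandscapeRealization) -> np.ndarray:
        """Per-NC fitness indexed by NC id, with an extra slot 0.0 for the
        deleterious class at index -1."""
        n_ncs = self.labeling.n_ncs
        arr = np.zeros(n_ncs + 1)
        for nc, f in realization.node_fitness.items():
            arr[nc] = f
        arr[n_ncs] = 0.0  # nc_of == -1 indexes here
        return arr


def sample_walk_start(
    engine: WalkEngine,
    realization: LandscapeRealization,
    rng: np.random.Generator,
) -> str:
    """Unbiased low-fitness start: a uniformly random genotype among all
    non-peak NCs whose fitness lies below the lowest-fitness peak.

    The NC is drawn with probability proportional to its size and the
    genotype uniformly within it, so every candidate genotype is equally
    likely overall.
    """
    peaks = {p.nc_id for p in find_peaks(realization)}
    min_peak_fitness = min(realization.node_fitness[nc] for nc in peaks)
    candidates = [
        nc
        for nc, f in realization.node_fitness.items()
        if nc not in peaks and f < min_peak_fitness
    ]
    if not candidates:
        raise EmptyStartSetError(
            "no non-peak NC lies below the lowest-fitness peak in this realization"
        )
    sizes = np.array([realization.nc_graph.size(nc) for nc in candidates], dtype=float)
    nc = candidates[rng.choice(len(candidates), p=sizes / sizes.sum())]
    idx = rng.choice(engine.genotype_indices_of_nc[nc])
    return engine.genotypes[idx]


def adaptive_walk(
    engine: WalkEngine,
    realization: LandscapeRealization,
    start: str,
    N: int = DEFAULT_POPULATION_SIZE,
    rng: np.random.Generator | None = None,
    peak_ncs: set[int] | None = None,
    variant: str = "haploid",
) -> WalkResult:
    """Run one SSWM walk from ``start`` until a peak NC is reached.

    Steps count accepted substitutions only.  A step cap guards against
    non-termination, but is unreachable in valid realizations because the
    loop condition is peak-NC membership.
    """
    if rng is None:
        rng = np.random.default_rng()
    if peak_ncs is None:
        peak_ncs = {p.nc_id for p in find_peaks(realization)}
    nc_fit = engine.nc_fitness_array(realization)
    cur = engine.index[start]
    if engine.nc_of[cur] < 0:
        raise ValueError(f"start genotype {start!r} is deleterious")
    steps = 0
    while engine.nc_of[cur] not in peak_ncs:
        if steps >= STEP_CAP:
            raise RuntimeError(f"walk exceeded the step cap of {STEP_CAP}")
        nbrs = engine.neighbors[cur]
        nbr_fit = nc_fit[engine.nc_of[nbrs]]
        cur_fit = nc_fit[engine.nc_of[cur]]
        uphill = nbr_fit >= cur_fit
        candidates = nbrs[uphill]
        weights = kimura_fixation_probability(cur_fit, nbr_fit[uphill], N, variant=variant)
        weights = np.atleast_1d(weights)
        cur = int(candidates[rng.choice(len(candidates), p=weights / weights.sum())])
        steps += 1
    end_nc = int(engine.nc_of[cur])
    return WalkResult(
        start=start,
        endpoint=engine.genotypes[cur],
        endpoint_nc=end_nc,
        endpoint_fitness=float(nc_fit[end_nc]),
        n_steps=steps,
    )


def walk_ensemble(
    gp_map: GPMap,
    distribution: DistributionSpec,
    n_walkers: int = 1000,
    n_pf_maps: int = 100,
    N: int = DEFAULT_POPULATION_SIZE,
    seed: int = 0,
    nc_graph: NCGraph | None = None,
    engine: WalkEngine | None = None,
    variant: str = "haploid",
) -> WalkEnsembleResult:
    """Run ``n_walkers`` walks on each of ``n_pf_maps`` PF realizations.

    PF maps whose realization admits no unbiased start (the lowest-fitness
    NC is itself a peak) are redrawn from a fresh substream and counted in
    ``n_redrawn_pf_maps``.  Fully deterministic for a fixed seed.
    """
    if engine is None:
        engine = WalkEngine(gp_map)
    if nc_graph is None:
        nc_graph = build_nc_graph(gp_map, engine.labeling)
    phenotypes = nc_graph.phenotypes + [gp_map.deleterious_label]
    pf_idx, end_nc, end_fit, n_steps = [], [], [], []
    visit_counts: dict[tuple[int, int], int] = {}
    peak_ncs_by_map: dict[int, frozenset[int]] = {}
    n_redrawn = 0
    for i in range(n_pf_maps):
        realization = None
        for attempt in range(1000):
            rng_pf = np.random.default_rng((seed, 1, i, attempt))
            pf = draw_pf_map(phenotypes, distribution, rng_pf, gp_map.deleterious_label)
            candidate = attach_fitness(nc_graph, pf)
            peaks = {p.nc_id for p in find_peaks(candidate)}
            min_peak = min(candidate.node_fitness[nc] for nc in peaks)
            if any(
                nc not in peaks and f < min_peak
                for nc, f in candidate.node_fitness.items()
            ):
                realization = candidate
                break
            n_redrawn += 1
        if realization is None:
            raise EmptyStartSetError(
                f"no valid walk start after 1000 PF draws for replicate {i}"
            )
        peak_ncs_by_map[i] = frozenset(peaks)
        rng_walk = np.random.default_rng((seed, 2, i))
        for w in range(n_walkers):
            start = sample_walk_start(engine, realization, rng_walk)
            res = adaptive_walk(
                engine, realization, start, N=N, rng=rng_walk, peak_ncs=peaks, variant=variant
            )
            pf_idx.append(i)
            end_nc.append(res.endpoint_nc)
            end_fit.append(res.endpoint_fitness)
            n_steps.append(res.n_steps)
            key = (i, res.endpoint_nc)
            visit_counts[key] = visit_counts.get(key, 0) + 1
    return WalkEnsembleResult(
        pf_index=np.array(pf_idx, dtype=np.int64),
        endpoint_nc=np.array(end_nc, dtype=np.int64),
        endpoint_fitness=np.array(end_fit),
        n_steps=np.array(n_steps, dtype=np.int64),
        n_pf_maps=n_pf_maps,
        n_walkers=n_walkers,
        n_redrawn_pf_maps=n_redrawn,
        peak_visit_counts=visit_counts,
        peak_ncs_by_map=peak_ncs_by_map,
    )
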