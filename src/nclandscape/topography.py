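"""Peaks, ruggedness, and their closed-form predictions.

An NC is a *peak* of a landscape realization when its fitness strictly
exceeds that of every NC-graph neighbor.  Under random phenotype-fitness
assignment every ranking of an NC against its eps distinct neighbor
phenotypes is equally likely, so

    P(NC is a peak) = 1 / (eps + 1),

the coarse-grained analog of the House-of-Cards result with eps + 1
replacing (K-1)L + 1 ranked values.  Linearity of expectation gives the
expected peak count  sum_i 1/(eps_i + 1)  and the expected ruggedness
(fraction of genotypes in peaks)  (1/K^L) sum_i |NC_i|/(eps_i + 1).

Conditional on being a peak, an NC's fitness is the maximum of eps + 1
i.i.d. draws, with CDF C_F(G)^(eps+1); mixing over NCs weighted by their
peak probabilities approximates the aggregate peak-height distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nc_graph import NCGraph
from .pf_maps import DistributionSpec, LandscapeRealization, draw_pf_map, attach_fitness

__all__ = [
    "PeakRecord",
    "TopographySummary",
    "find_peaks",
    "ruggedness_of_realization",
    "peak_probability",
    "expected_peak_count",
    "expected_ruggedness",
    "peak_height_cdf",
    "peak_height_moments",
    "aggregate_peak_height_cdf",
    "simulate_topography",
]


@dataclass(frozen=True)
class PeakRecord:
    nc_id: int
    phenotype: str
    fitness: float
    evolvability: int
    size: int
    replicate: int | None = None


@dataclass
class TopographySummary:
    """Monte Carlo topography results next to their analytic predictions."""

    n_replicates: int
    distribution: DistributionSpec
    peak_counts: np.ndarray
    ruggedness: np.ndarray
    predicted_peak_count: float
    predicted_ruggedness: float
    peak_heights_by_evolvability: dict[int, np.ndarray]

    @property
    def mean_peak_count(self) -> float:
        return float(self.peak_counts.mean())

    @property
    def mean_ruggedness(self) -> float:
        return float(self.ruggedness.mean())

    def percentile_band(self, lo: float = 20.0, hi: float = 80.0) -> dict[str, tuple[float, float]]:
        return {
            "peak_count": tuple(np.percentile(self.peak_counts, [lo, hi])),
            "ruggedness": tuple(np.percentile(self.ruggedness, [lo, hi])),
        }


def _tie_check(values: np.ndarray) -> None:
    if len(np.unique(values)) != len(values):
        raise ValueError("fitness tie between distinct phenotypes; realization is invalid")


def find_peaks(realization: LandscapeRealization, replicate: int | None = None) -> list[PeakRecord]:
    """All NCs strictly fitter than every NC-graph neighbor.

    Isolated NCs are always peaks; the global-optimum phenotype's NCs are
    peaks, so the result is never empty.
    """
    g = realization.nc_graph
    fit = realization.node_fitness
    phenotype_fitness = {}
    for nc in g.graph.nodes:
        phenotype_fitness[g.phenotype(nc)] = fit[nc]
    _tie_check(np.array(list(phenotype_fitness.values())))
    peaks = []
    for nc in g.graph.nodes:
        f = fit[nc]
        if all(fit[m] < f for m in g.graph.neighbors(nc)):
            peaks.append(
                PeakRecord(
                    nc_id=nc,
                    phenotype=g.phenotype(nc),
                    fitness=f,
                    evolvability=g.evolvability(nc),
                    size=g.size(nc),
                    replicate=replicate,
                )
            )
    return peaks


def ruggedness_of_realization(
    realization: LandscapeRealization, peaks: list[PeakRecord] | None = None
) -> float:
    """Fraction of all K^L genotypes lying in peak NCs."""
    if peaks is None:
        peaks = find_peaks(realization)
    total = realization.nc_graph.total_genotypes
    return sum(p.size for p in peaks) / total


def peak_probability(evolvability: int) -> float:
    """1/(eps+1): chance that a random ranking puts the NC above all its
    eps distinct neighbor phenotypes."""
    if evolvability < 0:
        raise ValueError("evolvability must be non-negative")
    return 1.0 / (evolvability + 1)


def expected_peak_count(nc_graph: NCGraph) -> float:
    """Sum of per-NC peak probabilities (linearity of expectation)."""
    return float(sum(peak_probability(nc_graph.evolvability(nc)) for nc in nc_graph.graph.nodes))


def expected_ruggedness(nc_graph: NCGraph) -> float:
    """(1/K^L) * sum_i |NC_i| / (eps_i + 1)."""
    num = sum(
        nc_graph.size(nc) * peak_probability(nc_graph.evolvability(nc))
        for nc in nc_graph.graph.nodes
    )
    return float(num / nc_graph.total_genotypes)


def peak_height_cdf(evolvability: int, distribution: DistributionSpec, G) -> np.ndarray | float:
    """CDF of a peak's fitness: C_F(G)^(eps+1), the maximum of eps+1 draws."""
    if evolvability < 0:
        raise ValueError("evolvability must be non-negative")
    return np.asarray(distribution.cdf(G)) ** (evolvability + 1) if np.ndim(G) else float(
        distribution.cdf(G) ** (evolvability + 1)
    )


def peak_height_moments(evolvability: int, distribution: DistributionSpec) -> tuple[float, float]:
    """Closed-form (mean, variance) of the peak height at a given evolvability.

    Uniform on [0,1): mean (eps+1)/(eps+2), variance (eps+1)/((eps+3)(eps+2)^2).
    Exponential rate lambda: mean = (1/lambda) * sum_{k=1}^{eps+1} 1/k and
    variance = (1/lambda^2) * sum_{k=1}^{eps+1} 1/k^2 (standard order-statistic
    results for the maximum of eps+1 draws).
    """
    if evolvability < 0:
        raise ValueError("evolvability must be non-negative")
    n = evolvability + 1
    if distribution.family == "uniform01":
        mean = n / (n + 1)
        var = n / ((n + 2) * (n + 1) ** 2)
        return float(mean), float(var)
    if distribution.family == "exponential":
        k = np.arange(1, n + 1, dtype=float)
        lam = distribution.rate
        return float(np.sum(1 / k) / lam), float(np.sum(1 / k**2) / lam**2)
    raise ValueError(f"unsupported family {distribution.family!r}")


def aggregate_peak_height_cdf(nc_graph: NCGraph, distribution: DistributionSpec, G):
    """Approximate CDF of peak heights across a whole landscape:

        [ sum_i C_F(G)^(eps_i+1)/(eps_i+1) ] / [ sum_i 1/(eps_i+1) ]

    The normalization uses the *mean* peak count, so the expression is a
    (typically very good) approximation rather than exact.
    """
    eps = np.array([nc_graph.evolvability(nc) for nc in nc_graph.nc_ids], dtype=float)
    c = np.asarray(distribution.cdf(G), dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    num = (c[:, None] ** (eps + 1) / (eps + 1)).sum(axis=1)
    den = (1.0 / (eps + 1)).sum()
    out = num / den
    return float(out[0]) if scalar else out


class _SimulationArrays:
    """Flat-array view of an NC graph for vectorized Monte Carlo."""

    def __init__(self, nc_graph: NCGraph):
        self.ids = nc_graph.nc_ids
        index = {nc: i for i, nc in enumerate(self.ids)}
        phenos: dict[str, int] = {}
        ph_idx = np.empty(len(self.ids), dtype=np.int64)
        for i, nc in enumerate(self.ids):
            ph_idx[i] = phenos.setdefault(nc_graph.phenotype(nc), len(phenos))
        self.phenotypes = list(phenos)
        self.ph_idx = ph_idx
        self.sizes = np.array([nc_graph.size(nc) for nc in self.ids], dtype=np.int64)
        self.eps = np.array([nc_graph.evolvability(nc) for nc in self.ids], dtype=np.int64)
        src, dst = [], []
        for a, b in nc_graph.graph.edges:
            src += [index[a], index[b]]
            dst += [index[b], index[a]]
        self.edge_src = np.array(src, dtype=np.int64)
        self.edge_dst = np.array(dst, dtype=np.int64)

    def node_fitness(self, phenotype_fitness: np.ndarray) -> np.ndarray:
        return phenotype_fitness[self.ph_idx]

    def peak_mask(self, fit: np.ndarray) -> np.ndarray:
        neighbor_max = np.full(len(fit), -np.inf)
        if len(self.edge_src):
            np.maximum.at(neighbor_max, self.edge_src, fit[self.edge_dst])
        return fit > neighbor_max


def simulate_topography(
    nc_graph: NCGraph,
    distribution: DistributionSpec,
    n_replicates: int = 1000,
    seed: int = 0,
    collect_peak_heights: bool = True,
) -> TopographySummary:
    """Monte Carlo over PF realizations: per-replicate peak counts,
    ruggedness, and per-evolvability peak-height samples.

    Replicate ``r`` draws from an independent substream derived from
    ``(seed, r)``, so results are reproducible and order-independent.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    arrays = _SimulationArrays(nc_graph)
    n_ph = len(arrays.phenotypes)
    counts = np.empty(n_replicates)
    rugged = np.empty(n_replicates)
    heights: dict[int, list[float]] = {int(e): [] for e in np.unique(arrays.eps)}
    total = nc_graph.total_genotypes
    for r in range(n_replicates):
        rng = np.random.default_rng((seed, r))
        fit_ph = distribution.sample(rng, n_ph)
        fit = arrays.node_fitness(fit_ph)
        mask = arrays.peak_mask(fit)
        counts[r] = mask.sum()
        rugged[r] = arrays.sizes[mask].sum() / total
        if collect_peak_heights:
            for e, f in zip(arrays.eps[mask], fit[mask]):
                heights[int(e)].append(float(f))
    return TopographySummary(
        n_replicates=n_replicates,
        distribution=distribution,
        peak_counts=counts,
        ruggedness=rugged,
        predicted_peak_count=expected_peak_count(nc_graph),
        predicted_ruggedness=expected_ruggedness(nc_graph),
        peak_heights_by_evolvability={e: np.array(v) for e, v in heights.items()},
    )
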