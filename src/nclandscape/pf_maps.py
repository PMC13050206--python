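"""Random phenotype-fitness (PF) maps and landscape realizations.

A PF map assigns one independent fitness draw to every non-deleterious
phenotype from a fixed distribution (uniform on [0, 1) by default, or
exponential with rate lambda); the deleterious phenotype is pinned to
fitness exactly 0.  Attaching a PF map to an NC graph yields a landscape
realization in which every NC inherits the fitness of its phenotype.

Because draws are continuous, ties between distinct non-deleterious
phenotypes occur with probability zero; a tie in a user-supplied PF map is
rejected, since every downstream quantity (peaks, ruggedness, navigability)
is defined through strict fitness comparisons and depends only on ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .nc_graph import NCGraph

__all__ = [
    "DistributionSpec",
    "PFMap",
    "LandscapeRealization",
    "draw_pf_map",
    "attach_fitness",
    "read_pf_map",
    "write_pf_map",
    "FitnessTieError",
]

FAMILIES = ("uniform01", "exponential")


class FitnessTieError(ValueError):
    """Two distinct non-deleterious phenotypes share a fitness value."""


@dataclass(frozen=True)
class DistributionSpec:
    """Family of the fitness distribution underlying a PF map.

    ``uniform01`` draws from [0, 1); ``exponential`` draws from an
    exponential with rate ``rate`` (default 1).
    """

    family: str = "uniform01"
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}; choose from {FAMILIES}")
        if self.family == "exponential" and self.rate <= 0:
            raise ValueError(f"exponential rate must be positive, got {self.rate}")

    @property
    def frozen(self):
        if self.family == "uniform01":
            return stats.uniform(loc=0.0, scale=1.0)
        return stats.expon(scale=1.0 / self.rate)

    @property
    def support_sup(self) -> float:
        return 1.0 if self.family == "uniform01" else math.inf

    def cdf(self, x) -> np.ndarray | float:
        return self.frozen.cdf(x)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "uniform01":
            return rng.random(size)
        return rng.exponential(scale=1.0 / self.rate, size=size)


@dataclass(frozen=True)
class PFMap:
    """Phenotype -> fitness table; deleterious phenotype pinned to 0."""

    fitness_of: dict[str, float]
    distribution: DistributionSpec | None
    deleterious_label: str = "DELETERIOUS"
    seed: int | None = None

    def fitness(self, phenotype: str) -> float:
        if phenotype == self.deleterious_label:
            return 0.0
        return self.fitness_of[phenotype]

    def validate_tie_free(self) -> None:
        values = [f for p, f in self.fitness_of.items() if p != self.deleterious_label]
        if len(set(values)) != len(values):
            raise FitnessTieError(
                "two distinct non-deleterious phenotypes share a fitness value; "
                "the random-ranking theory requires tie-free PF maps"
            )


@dataclass
class LandscapeRealization:
    """An NC graph with fitness attached to every node."""

    nc_graph: NCGraph
    pf_map: PFMap
    node_fitness: dict[int, float]

    def fitness(self, nc_id: int) -> float:
        return self.node_fitness[nc_id]


def draw_pf_map(
    phenotypes: list[str],
    distribution: DistributionSpec,
    rng: np.random.Generator | int,
    deleterious_label: str = "DELETERIOUS",
) -> PFMap:
    """Draw one i.i.d. fitness value per non-deleterious phenotype.

    ``rng`` may be a seeded :class:`numpy.random.Generator` or an integer
    seed; the same seed reproduces the same PF map exactly.
    """
    if not phenotypes:
        raise ValueError("phenotype list is empty")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    nondel = [p for p in phenotypes if p != deleterious_label]
    draws = distribution.sample(rng, len(nondel))
    fitness_of = dict(zip(nondel, draws.tolist()))
    if deleterious_label in phenotypes:
        fitness_of[deleterious_label] = 0.0
    pf = PFMap(
        fitness_of=fitness_of,
        distribution=distribution,
        deleterious_label=deleterious_label,
        seed=seed,
    )
    pf.validate_tie_free()
    return pf


def attach_fitness(nc_graph: NCGraph, pf_map: PFMap) -> LandscapeRealization:
    """Set each NC's fitness from its phenotype; reject ties."""
    pf_map.validate_tie_free()
    node_fitness: dict[int, float] = {}
    for nc in nc_graph.graph.nodes:
        phenotype = nc_graph.phenotype(nc)
        try:
            node_fitness[nc] = pf_map.fitness(phenotype)
        except KeyError:
            raise KeyError(f"phenotype {phenotype!r} of NC {nc} missing from the PF map") from None
    return LandscapeRealization(nc_graph=nc_graph, pf_map=pf_map, node_fitness=node_fitness)


def read_pf_map(
    path: str | Path,
    deleterious_label: str = "DELETERIOUS",
) -> PFMap:
    """Read a phenotype TAB fitness TSV; the result must be tie-free."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["phenotype", "fitness"],
        dtype={"phenotype": str}, keep_default_na=False,
    )
    fitness_of = {str(p): float(f) for p, f in zip(df["phenotype"], df["fitness"])}
    pf = PFMap(fitness_of=fitness_of, distribution=None, deleterious_label=deleterious_label)
    pf.validate_tie_free()
    return pf


def write_pf_map(pf_map: PFMap, path: str | Path) -> None:
    rows = sorted(pf_map.fitness_of.items())
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
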