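# nclandscape

Predicting and simulating the topography of fitness landscapes — how many
peaks they have, how high those peaks are, and whether evolution can reach
the global optimum — from the structure of the underlying
genotype–phenotype (GP) map.

## Who this is for

Researchers studying molecular evolution on genotype spaces: complete
model GP maps (the built-in stop-codon "Fibonacci" family), or any map a
user supplies as a genotype → phenotype table. The package is both a
library and a command-line tool (`nclandscape`).

## The model

A GP map assigns each of the `K^L` length-`L` sequences over a `K`-letter
alphabet one categorical phenotype; one designated *deleterious* phenotype
is pinned to fitness 0. The map is coarse-grained into **neutral
components (NCs)**: maximal sets of genotypes that share a phenotype and
are connected by single phenotype-preserving substitutions. The **NC
graph** has one node per NC — annotated with its size `|NC|` and its
**evolvability** ε, the number of distinct non-deleterious phenotypes
among its mutational neighbors — and an edge wherever a point mutation
joins two NCs.

Fitness is assigned at the phenotype level: one i.i.d. draw per
non-deleterious phenotype from a fixed distribution (uniform on [0, 1) or
exponential). Because every ranking of an NC against its ε distinct
neighbor phenotypes is equally likely,

- `P(NC is a peak) = 1 / (ε + 1)`,
- expected peak count `⟨N_peaks⟩ = Σ_i 1/(ε_i + 1)`,
- expected ruggedness `⟨r⟩ = (1/K^L) Σ_i |NC_i|/(ε_i + 1)`,
- conditional peak-height CDF `P(F ≤ G | peak) = C_F(G)^(ε+1)`
  (the maximum of ε+1 draws), with closed-form mean and variance,
- an aggregate peak-height CDF mixing all NCs by their peak probabilities.

On top of this the package runs strong-selection weak-mutation adaptive
walks on the full genotype space (Kimura fixation weights, population size
N = 1000 by default) and estimates **navigability** — the probability that
a fitness-monotone accessible path connects a random size-weighted start
NC to the highest-fitness phenotype — together with the closed-form
minimum-evolvability bound `ε̄ ≲ n_p((δ·n_p)^{1/n_p} − 1)` below which a
constant-evolvability NC graph is expected to be non-navigable.

Genotype-level brute-force oracles (independent code paths) validate the
NC-level pipeline exactly on small instances.

## Worked example

```python
from nclandscape import (
    FibonacciGPMap, DistributionSpec, build_nc_graph, decompose_into_ncs,
    expected_peak_count, expected_ruggedness, simulate_topography,
    estimate_navigability, geometric_mean_evolvability,
)

gp_map = FibonacciGPMap(length=3)          # K=3, stop letter "2"
graph = build_nc_graph(gp_map, decompose_into_ncs(gp_map))
print(f"NC graph: {graph.n_ncs} NCs, {graph.n_edges} edges")
print(f"expected peak count: {expected_peak_count(graph):.4f}")
print(f"expected ruggedness:  {expected_ruggedness(graph):.4f}")

dist = DistributionSpec("uniform01")
summary = simulate_topography(graph, dist, n_replicates=1000, seed=1)
print(f"simulated mean peak count: {summary.mean_peak_count:.4f}")
print(f"simulated mean ruggedness: {summary.mean_ruggedness:.4f}")

nav = estimate_navigability(graph, dist, n_pf_maps=500, n_sources=10, seed=1)
print(f"navigability: {nav.navigability:.3f}")
```

Output:

```
NC graph: 7 NCs, 15 edges
expected peak count: 1.3429
expected ruggedness:  0.1217
simulated mean peak count: 1.3240
simulated mean ruggedness: 0.1188
navigability: 0.950
```

The 27-genotype map decomposes into 7 NCs (one per phenotype, sizes
9, 3, 3, 1, 1, 1, 1; evolvabilities 6, 4, 4, 4, 4, 4, 4), giving the
analytic peak count `1/7 + 6/5 = 47/35 ≈ 1.3429` and ruggedness
`23/189 ≈ 0.1217`; 1000 random phenotype–fitness realizations agree
within sampling error, and 95% of accessibility trials find a
fitness-monotone path to the global optimum.

The same pipeline is available from the shell:

```sh
nclandscape nc-graph build --model fibonacci -L 8 --out nodes.tsv,edges.tsv
nclandscape topography simulate --graph nodes.tsv,edges.tsv --reps 1000 --seed 1 --out topo.json
nclandscape navigability bound --np 200 --delta 0.1
```

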