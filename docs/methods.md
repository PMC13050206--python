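# Methods

## Model and assumptions

The package operates on genotype–phenotype–fitness (GPF) maps assembled
in two stages. A GP map is a total function from all `K^L` sequences to
categorical phenotypes, with one designated deleterious phenotype; a
phenotype–fitness (PF) map then assigns one independent continuous draw
per non-deleterious phenotype and pins the deleterious phenotype to
fitness exactly 0. Random PF assignment is the neutral baseline: it
injects the GP map's structure into the landscape without imposing any
fitness correlations, and every downstream quantity depends on the draws
only through their ranks.

The central object is the NC graph. A neutral component (NC) is a maximal
set of genotypes with one phenotype, connected under single allowed
substitutions; deleterious genotypes carry no NC (they can never lie on
an accessible path and would only dilute the graph). NC evolvability ε
counts *distinct non-deleterious* phenotypes among an NC's neighbors.
Excluding the deleterious class from ε is deliberate: ε must count
exactly the competitors in a random fitness ranking, and a fitness-0
neighbor can never outrank a positive-fitness NC. `build_nc_graph`
exposes `include_deleterious_in_evolvability` for sensitivity analyses
only; nothing downstream uses it.

Key identities (all rank-based, distribution-free unless noted):

- peak probability `1/(ε+1)`; expected peak count `Σ 1/(ε_i+1)`;
  expected ruggedness `(1/K^L) Σ |NC_i|/(ε_i+1)`;
- conditional peak height = maximum of ε+1 i.i.d. draws, CDF
  `C_F(G)^(ε+1)`; uniform moments `(ε+1)/(ε+2)` and
  `(ε+1)/((ε+3)(ε+2)^2)`; exponential(λ) moments `(1/λ)Σ_{k≤ε+1} 1/k`
  and `(1/λ²)Σ_{k≤ε+1} 1/k²`;
- the aggregate peak-height CDF normalizes the mixture by the *expected*
  peak count, so it is an approximation (fluctuations in the realized
  count are ignored); tests hold it to a 0.02 sup-norm tolerance on the
  L=8 stop-codon map rather than claiming exactness;
- the navigability bound `n_p((δ n_p)^{1/n_p} − 1)` assumes one NC per
  phenotype, constant connection probability, and short paths; it is
  one-sided (low-ε graphs are non-navigable; nothing is claimed for
  high-ε graphs).

## Built-in GP maps

The stop-codon ("Fibonacci") model maps a genotype to its prefix before
the first stop letter (default alphabet `0,1,2`, stop `2`); genotypes
with no stop letter are deleterious. For K=3 this yields `2^L − 1`
non-deleterious phenotypes, each realized by a single NC of size
`3^(L−1−m)` for a prefix of length m. Two conventions are ours to fix,
both configurable: the empty prefix (stop in first position) is a valid
non-deleterious phenotype, because the cutting rule produces it naturally
and excluding it would add an extra rule; and user-facing positions are
1-based while internals are 0-based.

The low-evolvability variant forbids (a) mutating the first stop letter
and (b) introducing a stop letter strictly before it. A genotype without
a stop letter is assigned first-stop index L+1 (internally L), so rule
(b) prevents it from ever gaining a stop; this is the only convention
that keeps the mutation relation symmetric, which both the decomposition
and the undirected NC graph require. The variant preserves NC sizes
while strictly lowering evolvabilities — the designed low-ε test case.

## Simulation protocol and problem sizes

Defaults follow the standard protocol: 1000 PF realizations for
topography, 500 PF maps × 10 source phenotypes for navigability, and
1000 walkers on each of 100 PF maps for adaptive walks at population
size N = 1000. Replicate r draws from an independent substream seeded by
(seed, r), so runs are reproducible and order-independent. The test
suite exercises these protocols on the built-in maps at L = 3–8
(27–6561 genotypes), sizes at which the NC-level results can also be
verified exactly against genotype-level brute force; the acceptance
script uses a 200×50 walk ensemble on L = 5, ample for the endpoint
statistics it reports.

Adaptive walks run on the full genotype space, not the NC graph, so that
larger NCs — reachable from more genotypes — can attract more walkers.
Candidate moves are neighbors with fitness ≥ current (neutral steps
allowed; deleterious genotypes, having fitness 0, are never candidates),
weighted by Kimura fixation probability. The Kimura formula is named but
not printed in most treatments; we use the haploid form
`(1 − e^{−2s})/(1 − e^{−2Ns})` with `s = f'/f − 1` and neutral limit
`1/N`, with a diploid variant available — results are rank-driven and
robust to this choice. A "step" counts accepted substitutions only.
Walk starts are sampled unbiasedly from all non-peak NCs below the
lowest-fitness peak (size-weighted NC, uniform genotype within it); PF
maps where this set is empty are redrawn and counted, not silently
skipped, so the ensemble bookkeeping stays unbiased.

Navigability trials pick the target as the highest-fitness phenotype of
each PF map and compute reachability once per map by reverse search from
the target NCs — contractually identical to per-source forward search,
which the tests verify. Source phenotypes are drawn uniformly with
replacement and a source equal to the target counts as a success (the
length-0 path is accessible under any reading); `exclude_target_source`
provides the alternative convention.

## What the synthetic generators emulate

The constant-evolvability random graph (one unit-size NC per phenotype,
each pair connected with probability `ε̄/(n_p − 1)`) realizes exactly the
idealization behind the navigability bound. Real GP maps violate all of
its assumptions to some degree — multiple NCs per phenotype,
heterogeneous ε, genotype-space locality of connections — so passing the
bound-regime tests validates the bound's own regime, not its sharpness
on empirical maps. Likewise the built-in stop-codon maps are highly
structured (one NC per phenotype, strong size–evolvability coupling);
tests passing on them demonstrate the machinery and the closed forms,
not distributional claims about biophysical maps, which users can load
as TSV tables.

## Numerical choices

- Strict inequality defines peaks; fitness ties between distinct
  non-deleterious phenotypes are rejected as errors (probability zero
  under continuous draws; possible only in user-supplied PF maps).
- Geometric mean evolvability replaces ε = 0 by 0.01 so one isolated NC
  cannot zero the mean; the replacement is a parameter.
- Percentile bands (20th–80th) use linear interpolation.
- Peak heights are binned by exact ε value, no bucketing.
- Acceptance-style Monte Carlo comparisons use 3-standard-error bands;
  per-ε moment checks require at least 30 samples in a class before
  comparing, since below that the fourth-moment variance estimate is
  itself too noisy to define a band.
- Uniform draws live on [0, 1); the boundary has measure zero.
- Enumeration is capped (default 10^8 genotypes) with an explicit error;
  brute-force oracles cap at 4096 genotypes and permutation enumeration
  at 8 phenotypes.

## Design choices where the design was open

- NC ids are assigned in order of first-visited genotype under
  lexicographic enumeration, making decompositions and all serialized
  outputs deterministic; the union-find oracle reproduces the same ids
  independently by ranking components by their smallest genotype.
- Merging NCs by phenotype is provided as a separate, idempotent graph
  transform (used to conservatively upper-bound navigability-relevant
  evolvability), never applied implicitly.
- Only the global-optimum-target definition of navigability is
  implemented; averaged over PF maps it is equivalent to sampling a
  target and promoting it, and one definition keeps the estimator
  simple.
- Oracles share no graph code with the pipeline (only the GP-map
  contract); their agreement is asserted exactly, never within a
  tolerance.

## Known limitations

- No weighted NC graphs (mutation multiplicities as edge weights) and no
  correlated or target-based PF maps; the random-assignment baseline is
  the scope.
- The walk model is a single SSWM walker, not a polymorphic population.
- Constructing biophysical GP maps (RNA folding, protein models,
  self-assembly) is out of scope; such maps enter only as user-supplied
  tables.
- The aggregate peak-height CDF and the evolvability bound are
  approximations by construction; the tests document their tolerances
  rather than sharpening them.
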