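# Methods

## The demographic model family

Four two-deme divergence histories are parameterized by a single
`DemographicModel`. Backwards in time, clusters I and II keep sizes
(N_CLI_0, N_CLII_0) on [0, T₁), switch instantaneously to
(N_CLI_1, N_CLII_1) on [T₁, T₂), and merge at T₂ into a panmictic
ancestor of size N_ANC. Migration is parameterized as Nm_{i–j}, the
expected number of migrant **gene copies** per generation moving from
cluster j into cluster i forward in time, and is active in a
model-specific window:

| model | window            | free parameters |
|-------|-------------------|-----------------|
| 1     | none              | 7               |
| 2     | present → T₂      | 9               |
| 3     | T₁ → T₂           | 9               |
| 4     | present → T₁      | 9               |

Conventions that differ between simulators and are therefore fixed
explicitly here:

* **Sizes are diploid.** A deme of size N holds 2N gene copies; a pair
  of lineages coalesces at rate 1/(2N) per generation.
* **Backward migration rate.** A lineage currently in deme i jumps to
  deme j at rate Nm_{i–j}/(2N_i): the forward flow j→i of Nm gene copies
  per generation into a pool of 2N_i copies. With two demes this makes
  the Weir–Cockerham θ expectation under symmetric equilibrium migration
  exactly 1/(1 + 4Nm), which the island-model tests exploit.
* Time is continuous, in generations; changes at T₁/T₂ are
  instantaneous; T₂ > T₁ > 0 is enforced by fitting ΔT = T₂ − T₁.
* Mutation is infinite-sites within a locus at μ per site per
  generation; the default μ = 5.39 × 10⁻⁸ and the locus geometry
  (1753 loci × 138 bp ≈ 242 kb) mirror the study data. Recurrent-hit
  collisions at 138 bp are negligible at this μ and are ignored.

## Simulation engine

Genealogies are generated by an exponential race over within-deme
coalescence and per-lineage migration with piecewise-constant rates
(numba-compiled; ~10⁴ genealogies of 374 tips per second). Expected
spectra use a Rao-Blackwellized estimator: each branch's length is
credited to its joint (descendants-in-I, descendants-in-II) cell, so the
expected folded SFS is μ × the mean branch length per cell, folded on
the global minor allele. This removes the Poisson mutation noise from
every likelihood evaluation and is why a few thousand genealogies
suffice where mutation-dropping Monte Carlo would need far more.
Realized (finite-data) spectra draw Poisson counts per cell on top of
the same branch totals; genotype-level simulation records full tree
topologies and drops mutations branch by branch.

## Composite likelihood and fitting

The observed folded joint SFS is multinomial over frequency cells;
LL = Σ m·log₁₀ p̂. Two design points:

* **Monomorphic cell included by default.** With polymorphic cells only,
  scaling every size and time by a constant leaves the normalized
  spectrum unchanged — absolute parameters are unidentifiable. The
  monomorphic count (total sites − SNPs) anchors the scale through the
  per-site polymorphism probability. A `with_monomorphic=False` switch
  provides the shape-only likelihood.
* **Zero-cell floor.** Finite simulation leaves some observed cells with
  p̂ = 0; these are floored at 1/(10·n_sims·n_cells) to keep LL finite.
  The floor shrinks with simulation effort, so LL values are comparable
  only at equal `n_coal_sims`.

Optimization is expectation-conditional-maximization flavoured: from
each start, one bracketed golden-section line search per parameter per
cycle on the log₁₀ scale, all evaluations sharing common random numbers
(LL is then a deterministic function of the parameters and the per-cycle
trace is non-decreasing at constant fidelity). The first ~60% of cycles
run at a quarter of the simulation effort. Starts are the best
log-uniform random candidates from a screened pool **plus four
data-informed starts**: Watterson-type size estimates from the
within-cluster marginal segregating-site counts, with the divergence
time swept over a log grid (0.5–32 × the average size estimate), since
divergence time is the least-identified axis and random 9-dimensional
candidates rarely land in its basin. The reported LL is a fresh
evaluation at an independent seed, so best-of-starts selection is not
biased by noise adapted to during the search.

Search ranges default to 10²–10⁶ (sizes, diploid), 10²–10⁷ generations
(T₁ and ΔT) and 10⁻²–10² (Nm). AIC = 2·NP − 2·ln(10)·LL; the lowest-AIC
model wins. Confidence intervals are parametric-bootstrap percentiles:
datasets simulated at the MLE with the observed geometry, each refit
starting from the MLE at reduced cycle counts. Derived quantities
(size-change ratios, times in ka at 20 years/generation) are computed
per replicate and summarized; a ratio or Nm is flagged significant when
its 95% interval excludes 1.0.

## Synthetic data: what it does and does not emulate

The generator reproduces the study's sampling design (14 populations in
clusters of 106 and 81 diploids), data geometry (1753 × 138 bp,
~242 kb), per-call missingness (default 10%, i.i.d.), and a
1D-transect coordinate layout so isolation-by-distance has signal by
construction. Two deliberate simplifications:

* **No within-cluster substructure.** The demographic models have two
  demes; population labels are a random partition of each cluster's
  diploids. Per-population statistics on synthetic data are therefore
  near-identical within a cluster, unlike the mild real-world
  among-population structure, and population-level F_ST/Mantel results
  on synthetic data test machinery, not biology.
* **Missingness is i.i.d. per call**, not clustered by sample coverage.
  Strict presence filters (r ≥ 0.90 in every population) therefore
  retain almost nothing at 10% missingness, whereas real data with
  variable per-sample coverage retains a few loci; the filter semantics
  are tested against exhaustive scans, not against the published
  survivor counts.

Consequently, passing tests demonstrate correctness of the statistics,
spectra, simulator and fitting machinery under known truth — they do not
reproduce diversity-table values, which would require the archived
sequencing data.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so the full test suite and the
acceptance script each run in minutes on one CPU: recovery and
model-comparison fits use 300 loci (~700–800 SNPs), 8 ECM cycles, 4000
genealogies per evaluation and one screened random start plus the four
informed starts; bootstrap tests use ≤ 10 replicates. The study-scale
protocol (50 starts, 40 cycles, 10⁵ simulations, 100 bootstrap
replicates) is expressible through `FitConfig` but takes hours.
Divergence-time recovery at the reduced scale lands inside the reported
95% interval (292–671 ka); individual size parameters are noisier at 300
loci than at the full 1753.

Other numerical fixings: F_IS is the per-locus (H_E − H_O)/H_E averaged
over polymorphic loci; allelic-richness rarefaction defaults to the
smallest per-group gene count per locus; the multilocus θ is the ratio
of summed variance components; Mantel permutations relabel rows and
columns jointly and the p-value is one-tailed with the +1 correction;
exact-half SFS folds contribute ½ to each complementary cell; the
missing-data bootstrap resamples gene copies (not diploid genotypes)
within the cluster, so the expected imputed frequency equals the
observed cluster frequency; imputation runs once per analysis by
default, with the seed recorded in the spectrum.

## Known limitations

No recombination within loci, no selection, no sequencing-error model,
at most two demes/clusters for demographic fitting (>2 allowed for
diversity statistics only). Composite-likelihood AICs ignore linkage
between SNPs of a locus (standard for SFS methods; single-SNP thinning
mitigates it for the diversity panel but the SFS uses all SNPs). The
likelihood floor makes absolute LL values simulation-effort dependent;
comparisons are always made at matched effort and common random numbers.
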