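# karstdemog

Demographic inference for a two-cluster population of an endangered
karst-endemic shrub, genotyped at a few thousand reduced-representation
SNPs. The package re-implements the full analysis chain as a tested
library:

1. **Genotype I/O** — multi-sample VCF (GT-only) into a dense diploid
   genotype matrix, with a sample → population → cluster map.
2. **SNP filtering** — `populations`-style filters: per-population
   presence (-p/-r), pooled minor-allele frequency (`--min-maf`),
   observed-heterozygosity ceiling (`--max-obs-het`), first-SNP-per-locus.
3. **Diversity statistics** — H_O, H_E, F_IS, private alleles, rarefied
   allelic richness, nucleotide diversity, Weir–Cockerham F_ST, Nei (1972)
   distance, Mantel isolation-by-distance test.
4. **Folded joint SFS** — the 2D minor-allele site frequency spectrum of
   the two clusters, with within-cluster bootstrap imputation of missing
   genotypes.
5. **Coalescent engine** — a structured-coalescent simulator for four
   two-deme divergence models (isolation; isolation-with-migration;
   ancient migration; secondary contact) with staged population sizes.
6. **Model fitting** — maximum composite likelihood of the observed SFS
   (multinomial over frequency cells, expected probabilities by
   simulation), AIC model selection, parametric-bootstrap 95% CIs, and
   unit conversions (generations → ka at 20 y/generation).
7. **Synthetic data** — study-shaped datasets (14 populations, 106 + 81
   diploids, 1753 × 138 bp loci, per-call missingness) with known
   generating truth, so the whole pipeline is testable end to end.

## The model

Two clusters (I and II) diverged from an ancestor of size N_ANC at time
T₂, with independent sizes in the periods [0, T₁) and [T₁, T₂) and
migration Nm_{i–j} (migrant gene copies per generation, forward in time
from cluster j into i) active in a model-specific window. The observed
statistic is the folded joint SFS **m**, treated as multinomial:

LL = Σ_cells m_cell · log₁₀ p̂_cell,  AIC = 2·NP − 2·ln(10)·LL,

with p̂ estimated from simulated genealogies (expected branch length per
joint frequency cell × mutation rate; μ = 5.39 × 10⁻⁸ /site/generation).

## Worked example

```python
from karstdemog import (StudyShape, default_model, make_dataset,
                        build_folded_2dsfs, FitConfig, fit_model)

shape = StudyShape(n_loci=300, missingness=0.0)
gm, popmap, truth = make_dataset(shape, default_model(), seed=42)
obs = build_folded_2dsfs(gm, popmap)
fit = fit_model(obs, model_id=2,
                cfg=FitConfig(n_starts=1, n_ecm_cycles=8,
                              n_coal_sims=4000, seed=7))
t2_ka = (fit.params["t1"] + fit.params["dt"]) * 20 / 1e3
print(f"LL = {fit.ll:.1f}, T2 = {t2_ka:.0f} ka")
```

prints (a few minutes on one CPU):

```
LL = -4009.0, T2 = 413 ka
```

i.e. refitting the isolation-with-migration model to 300 loci simulated
at the published estimates recovers the divergence time (generating value
490 ka) inside the reported 95% interval (292–671 ka).

The `analysis/` scripts run the same chain as a narrative pipeline
(01 simulate → 02 filter → 03 diversity → 04 SFS → 05 fit + AIC →
06 bootstrap CIs), writing tables under `results/`.

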