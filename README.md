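# rareburden

Rare-allele burden analysis of population gene expression.

In a population, deleterious genetic variants are held at low frequency by
purifying selection. Under stabilizing selection on gene expression, such
rare variants (minor allele frequency < 5%) are expected to push their
carriers' expression away from the intermediate optimum — in either
direction — so carriers of rare *cis* variants should be over-represented
at both extremes when the samples of a population are ranked by each gene's
expression. `rareburden` implements this rank-based analysis for a selfing
crop population (e.g. rice landraces) assayed under two field conditions,
together with a synthetic-data generator so every stage of the pipeline is
verifiable without external data.

## The statistics

For each gene, the N samples are ranked by mean expression (rank 1 =
lowest), and the number of rare-variant sites at which each sample carries
the minor allele is counted in the gene body plus the 2 kb upstream of the
strand-aware TSS (*cis* mode), or in 2 kb distance windows out to >20 kb
(*windows* mode). Averaging the counts per rank across genes gives the
per-rank profile, whose U-shape is summarized three ways:

* a quadratic OLS fit, mean count ~ a + b·x + c·x² in the rank percentile
  x, with r² and the model F-test (c > 0 means convex/U-shaped);
* two-sided Mann–Whitney tests comparing the per-rank means of the top and
  bottom 20% of ranks against the middle 40–60%;
* the extreme-to-middle ratio **φ = E_r/M_r**, where E_r totals the carrier
  counts in the lowest and highest 10% of ranks and M_r in the middle
  40–60% block (classes rounded to equal rank mass, so φ = 1 under no
  association).

Two φ values — from two conditions or two strata — are compared by Fisher's
exact test on the 2×2 table [[E_A, M_A], [E_B, M_B]], whose sample odds
ratio equals φ_A/φ_B exactly, and across conditions also by a permutation
test that shuffles the sample-to-rank assignment within every gene. Strata
cover variant class (SNP/indel/SV), distance window, recombination rate,
fitness-consequence (fitCons ρ) score, expression level, and co-expression
network connectivity.

Variant preparation implements the population-calling filters: GATK-style
hard quality thresholds for SNPs and indels (≤ 20 bp), duphold-style depth
fold-change filters for deletions/duplications, a 20 bp – 200 kb SV size
window, removal of within-sample overlapping SV calls, 50%-reciprocal /
1 kb-breakend single-linkage SV merging across samples (exact position
match for breakends), and rare-variant selection at folded MAF < 5% with a
class-specific evidence rule (≥ 1 homozygote or ≥ 3 heterozygotes for
SNPs/indels; singleton SVs allowed).

## Worked example

```python
import rareburden as rb

sim = rb.simulate(rb.SimConfig.scaled(300, seed=11))   # synthetic population
res = rb.RareBurdenModel.from_simulation(sim, "wet").fit()
print(res.summary())
```

```
Rare-allele burden analysis
==============================================
condition:          wet
region bins:        GENIC + U_0_2 (cis mode)
genes analysed:     300
rare variants:      7725
samples:            129
----------------------------------------------
quadratic fit  mean count ~ a + b*x + c*x^2
  a (intercept):     0.4681
  b (linear):       -0.4322
  c (quadratic):     0.4387   convex (U-shaped)
  r^2:               0.3489
  F-test p:          1.82e-12
  MW high_vs_mid   U = 437.0, p = 0.0355 (asymptotic)
  MW low_vs_mid    U = 500.5, p = 0.000964 (asymptotic)
----------------------------------------------
extreme counts E_r: 3595
middle counts  M_r: 2993
phi = E_r/M_r:      1.2011
```

The positive curvature (c = 0.44, r² = 0.35) and φ = 1.20 recover the
planted rare-variant effect: samples at the expression extremes carry more
rare *cis* variants than samples at middle ranks. Comparing conditions:

```python
dry = rb.RareBurdenModel.from_simulation(sim, "dry").fit()
cmp_ = dry.compare(res)          # Fisher on [[E_dry, M_dry], [E_wet, M_wet]]
print(cmp_.odds_ratio, cmp_.fisher_p)          # 1.1383  0.00024
print(dry.permutation_test(res, n_perm=199, seed=1))   # 0.005
```

The generator plants stress-amplified effects (κ_dry = 1.3), and both tests
detect the stronger burden under drought.

The same analysis runs from standard files (VCF + GFF3 + expression TSV)
via `rb.RareBurdenModel.from_files(...)`, through `rareburden.run_stratified`
for the full condition × factor grid, or from the shell:

```bash
rareburden simulate --out data/ --seed 1 --n-genes 500
rareburden report --dir data/
rareburden stratify --dir data/ --out results/grid
```

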