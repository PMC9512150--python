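# Methods

## The model

The package tests a single hypothesis about a population: carriers of rare
genetic variants (folded minor allele frequency < 5%) near a gene are
over-represented at that gene's expression extremes. Under stabilizing
selection on expression, deleterious regulatory variants — which selection
keeps rare — perturb expression away from an intermediate optimum in either
direction, so the signature is symmetric: a U-shaped excess of rare-variant
carriers at both the low and high tails of the within-population expression
ranking, not a mean shift.

The unit of analysis is the (gene, sample) pair. For each gene, samples are
ranked by mean expression across replicates (rank 1 = lowest, ties broken
deterministically by panel order), and each sample's burden is the number
of rare-variant sites in the gene's *cis* region at which it carries the
minor allele. Counting is presence-based (het and hom carriers both
contribute 1); a dosage-weighted option exists but is off by default, since
in a predominantly selfing population almost all carriers are homozygous
and presence is the natural reading of "number of rare variants carried".

### Region assignment

The *cis* region is the gene body plus the 0–2 kb window upstream of the
strand-aware TSS. The windows mode extends this to 2 kb bins out to 20 kb
plus a distal >20 kb bin, capped at 100 kb to bound the search. Windows are
measured from the TSS, extend away from the gene, and are deliberately not
truncated at neighbouring genes (no truncation rule is defensible without
annotation of regulatory domains; the synthetic generator sidesteps the
issue by spacing genes so windows never collide). Point variants (SNPs,
indels, breakends) are assigned by position; structural variants by any
overlap of their interval, so a deletion spanning the gene boundary counts
in both GENIC and U_0_2 — the only rule that respects SV extent. A variant
within reach of two genes is assigned to both.

### Summaries of the per-rank profile

* **Quadratic fit.** Mean count per rank is regressed on the rank-midpoint
  percentile x = (r − 0.5)/N and x² by OLS; r², the model F-test p, and the
  sign of the quadratic coefficient are reported. Percentile, not raw rank,
  is the regressor so fits are comparable across panel sizes. A flat
  profile short-circuits to r² = 0, c = 0 (zero total sum of squares).
* **Rank-group tests.** Per-rank means of the bottom 20% and top 20% of
  ranks are each compared to the middle 40–60% by a two-sided Mann–Whitney
  U test: exact null enumeration when both groups have ≤ 8 untied values,
  otherwise the tie-corrected normal approximation.
* **φ = E_r/M_r.** E_r totals carrier counts over the lowest 10% plus
  highest 10% of each gene's ranks, M_r over the middle 40–60% block.

### Equal-mass rank classes for φ

The nominal class definitions (10% tails, 40–60% middle) are converted to
whole ranks per gene by rounding half-up: the lowest and highest
round(0.1 n) ranks are extreme and the centered round(0.2 n)-rank block is
the middle. This guarantees the two classes span exactly equal rank mass
for every panel size, which is what makes φ = 1 the no-association
baseline. The alternative — classifying by percentile intervals with
half-open boundaries — silently breaks this at most panel sizes: at
N = 129 it puts 26 ranks in the extreme class but 25 in the middle, so
even exchangeable counts give E[φ] = 26/25 = 1.04, a bias the size of the
biological contrasts being measured. Null simulations with the equal-mass
classes centre on φ = 1.00 (SD ≈ 0.008 at 2000 genes).

### Comparing two φ values

Strata are compared by Fisher's exact test (two-sided, by summation of
tables with point probability ≤ observed) on [[E_A, M_A], [E_B, M_B]]; the
sample odds ratio of this table is algebraically φ_A/φ_B, which is why the
odds ratio is reported as the effect size of a stratum contrast. Conditions
are additionally compared by a permutation test: within every gene, in both
datasets, the sample-to-rank assignment is permuted (equivalently the
gene's counts are shuffled among its ranked samples), Δφ recomputed, and
p = (1 + #{|Δφ_perm| ≥ |Δφ_obs|})/(n_perm + 1). The add-one correction
keeps p > 0 and finite-resampling valid. What is permuted was a genuinely
open choice; permuting within genes breaks exactly the genotype–expression
link while preserving both the burden structure (which samples carry how
much, per gene) and the rank structure, and is therefore the implemented
null.

## Variant and expression preparation

* Hard filters (SNPs: QD > 2, FS < 60, MQ > 40, SOR < 4, MQRankSum > −12.5,
  ReadPosRankSum > −8; indels: QD > 2, FS < 200, SOR < 10, length ≤ 20 bp).
  A missing annotation passes its criterion: the rank-sum annotations are
  only emitted at sites with heterozygous calls, and failing them would
  silently drop every hom-only site.
* SV filters: deletions need depth fold-change vs flanks < 0.70,
  duplications vs GC-matched bins > 1.30 (missing fold-change → removed,
  conservatively); non-breakend SVs must satisfy 20 bp < length ≤ 200 kb.
* Within one sample, overlapping SV calls (possible complex rearrangements)
  are removed pairwise before merging; abutting inclusive intervals do not
  overlap.
* Cross-sample SV merging is single-linkage at ≥ 50% reciprocal overlap
  with both breakends within 1 kb; breakend records merge only on exact
  position. Each cluster is represented by its first member by (pos, end) —
  a deterministic choice that makes merge output exactly testable — with
  the union (max alt count) of member genotypes.
* Allele frequency excludes missing calls from numerator and denominator;
  the minor allele is frequency-defined (if the alternate allele is the
  major one, carriers are reference carriers). Rarity is folded
  MAF < 0.05 plus, for SNPs/indels, ≥ 1 minor-allele homozygote or ≥ 3
  heterozygotes (guarding against singleton-het genotyping error);
  SV singletons are allowed. The catalog is computed once on the full
  panel and reused across conditions.
* Expression: genes are analysed if non-zero in ≥ 2 of 3 replicates in at
  least floor(0.85 × N) samples; genes with > 50% reciprocal overlap with a
  transposable element are removed (strict inequality on both sides);
  replicates are averaged arithmetically over present values; zero-mean
  samples still receive (low) ranks, since dropping them would hollow out
  the low tail. Genes ranked over fewer than 10 samples are excluded from
  rank analyses.

## Stratification

Recombination rate and (per condition) mean expression are median-split
with ties going to `low`; fitCons scores split SNPs into high (ρ > 0.2) and
low (ρ < 0.1) with the band between excluded; connectivity uses the fixed
ranges high r ∈ [0.80, 0.99], low r ∈ [0.16, 0.77], values outside either
range excluded rather than clamped. Unclassifiable items always get an
explicit `excluded` label, never silent removal, so every factor partitions
its items. The fitCons split filters variants (all genes retained); the
gene-level splits filter genes (all variants retained).

## The synthetic-data generator

`synthio.simulate` emulates the study design: 129 diploid, mostly
homozygous (selfing fraction 0.95) samples; rare SNPs/indels/SVs placed in
gene bodies (40%) and upstream windows (decaying mixture out to 100 kb),
with carrier counts drawn so folded MAF < 5% holds by construction and the
class evidence rules are satisfied for SNP/indel records; common variants
that fail the frequency filter; and a block of two-heterozygote SNPs that
are rare by frequency but fail the evidence rule, to exercise that filter.
Missing genotype calls are placed only on major-allele homozygotes of
common variants, so the generated rare/common partition matches the
selection function exactly rather than probabilistically.

Expression per condition is baseline (gene optimum ~ U(2, 8) on the
log2(TPM+1) scale) + between-sample noise (SD 1.0) + planted genetic
shifts, with three replicates (technical SD 0.25), 2% dropout to zero, and
clipping at 0. A causal subset of rare variants (default fractions 0.20 /
0.25 / 0.30 for SNP/indel/SV) shifts each carrier's expected expression by
±δ (default 1.0 between-sample SD, symmetric signs to produce the U-shape;
a per-class sign-bias option can skew SV/indel effects downward). Effects
decay with TSS distance as exp(−d/λ), λ = 2 kb, are full-strength inside
the gene, and are multiplied by κ_dry = 1.3 under stress. The causal
probability is coupled to low recombination rank, low expression rank and
high ρ (linear weights), so the stratified contrasts have planted truth to
recover. Where the emulated study does not state a generator value, these
defaults were chosen once as field-realistic and are not tuned.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and haplotype structure
(each variant's carriers are drawn independently), population structure
and kinship, shared environment/batch effects between conditions, mapping
or reference bias, overlapping genes and shared regulatory regions, and
count-distribution artefacts of 3′ tag sequencing. Effect recovery on this
generator demonstrates correctness of the machinery, not robustness of the
statistic to those confounders.

## Problem sizes and numerics

Null calibration uses 100 seeds at the full study scale (129 samples,
2000 genes, ~51,500 rare variants), where φ's null SD is ≈ 0.008; signal
recovery and stratum contrasts use 500–800-gene panels with variant counts
scaled proportionally (`SimConfig.scaled`), where planted contrasts are an
order of magnitude larger than sampling noise. Permutation tests default to
1000 permutations (99–500 in tests, sized to their granularity needs).
Rank ties are broken by panel order so every pipeline output is exactly
reproducible; a seeded random tie-break exists for sensitivity analysis.
Degenerate inputs fail loudly: genes without strand, ρ outside [0, 1],
zero-margin contingency tables, quadratic fits on < 4 points, empty rank
groups.

## Known limitations

* Breakend partners are not paired; each BND record counts as one variant
  at its position (and merges only on exact position match).
* Single-linkage SV merging can chain calls that pairwise fail the
  reciprocal-overlap rule; with the 1 kb breakend window the effect is
  bounded, but an all-pairs criterion would be stricter.
* The >20 kb window is capped at 100 kb; variants beyond that are simply
  unassigned.
* φ has no analytic uncertainty attached; comparisons rely on the Fisher
  and permutation machinery rather than per-φ confidence intervals.
* The condition comparison assumes the same rare-variant catalog in both
  conditions (true here by design; the catalog is frequency-based only).
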