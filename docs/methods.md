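# Methods

This note documents the statistical models, the defaults that matter, the
synthetic-data generator, and the design choices that were genuinely open.

## Mixed linear model scan

Each trait is analyzed separately under

    y = X b + g + e,    g ~ N(0, σ²_g K),    e ~ N(0, σ²_e I)

with `K` the VanRaden genomic relationship matrix computed from
frequency-centered dosages, `K = ZZᵀ / (2 Σ pᵢ(1−pᵢ))`, after per-SNP mean
imputation of missing calls and exclusion of monomorphic SNPs. On a fully
inbred panel (dosages 0/2) the diagonal of `K` sits near 2 rather than 1;
only the relative structure of `K` matters to the test, and the REML scale
parameter absorbs the rest.

Variance components come from REML profiled over `δ = σ²_e/σ²_g`: after one
eigendecomposition `K = U S Uᵀ`, the rotated model is heteroscedastic-
diagonal, and the profiled restricted likelihood is maximized by Brent's
bounded search on `log₁₀ δ ∈ [−5, 5]` (xatol 1e-8). When the profile is
flat (e.g. `K = I`) only `σ²_g + σ²_e` is identified; the fit is flagged
`delta_identifiable = False` and any point on the ridge is accepted.

Per-SNP testing uses P3D: the null variance components are reused for every
SNP and the dosage effect is tested by a GLS F test with the residual scale
re-estimated per SNP (1 and n−p−1 df). With `K = I` and no covariates this
reduces *exactly* to the ordinary least-squares F test, which the tests use
as an oracle. `p3d=False` re-estimates δ per SNP through a dense path.
SNPs with missing dosages are handled by case-wise deletion through a dense
GLS solve on the subset covariance; complete SNPs take the fast rotated
path. The two paths are statistically identical.

Covariates are an intercept plus the top principal components of the
centered dosage matrix. The number of PCs (0..k_max, default k_max 5) is
chosen by BIC of the null mixed model under full ML,
`BIC = −2ℓ + (k + 3) ln n`, ties to the smaller k — emulating
model-selection-based PC choice. PCA signs are fixed by making each
component's largest-magnitude loading positive, so results are
deterministic.

**Favorable allele effect (FAE).** The reported effect is per copy of the
*minor* allele with the major allele as zero reference (the
major-allele-zero convention), so that a positive FAE always means "the
rarer germplasm allele raises the trait". At an exact frequency tie the REF
allele stays the reference and the SNP is flagged. The MAF threshold is
0.01 (configurable); sub-threshold SNPs are emitted untested with a
`low_maf` flag.

**Genomic control.** λ is the median association χ² over the null median
(0.4549). On stratified null panels the corrected scan (kinship + selected
PCs) sits near 1 while an uncorrected OLS scan inflates severely; both are
exercised in the tests and the acceptance script.

## Locus calling and clustering

Dual-threshold calling: SNPs at −log₁₀(P) ≥ 6.0 always qualify; SNPs in
[3.0, 6.0) qualify only inside a same-trait support interval (linkage or
literature QTL), trading type-II error against independent evidence.
Qualifying SNPs within `merge_gap` (default 300 kb) merge into one locus;
the locus takes the span of its SNPs, the peak −log₁₀(P) and the peak
SNP's FAE. Published tables do not state how locus ranges were delimited,
so the merge gap is an explicit, configurable choice. Loci are named
`q<Trait><chrom>[-k]`, the `-k` suffix only when a chromosome carries more
than one locus of that trait.

Cd loci are chained into clusters by single linkage: consecutive
same-chromosome loci join when `next.start − prev.end ≤ max_gap` (default
3 Mb), labels `Clst<chrom><a,b,…>` in positional order. The published
cluster memberships are not consistent with any single gap value (one
printed cluster has an internal gap larger than the gap separating two
other printed clusters), so the original rule is unrecoverable:
fixture-derived summaries therefore use the *printed* labels, while
`cluster_cd_loci` governs new data. Two further printed statements — "16
clusters with ≥2 loci" alongside "14 singleton clusters" among 29 (sums to
30), and "mean 3.6 loci/cluster" — cannot both be right; the fixture
recount gives 15 multi-locus and 14 singleton clusters and a mean of
62/29 ≈ 2.1. The package reports the recounted values.

Direction and favorability: a locus is *increasing* iff FAE > 0 and
*favorable* iff the FAE sign matches the trait polarity (+ for Fe, Zn, Mn,
Cu, Se; − for Cd). FAE exactly 0 is counted as neither and logged (it does
not occur in the packaged table).

## Comparative mapping

A locus is supported by an external interval iff the ranges intersect by at
least 1 bp on the same chromosome, 1-based inclusive (touching endpoints
count), and — by default — the traits match; a Cd locus is only confirmed
by a Cd QTL. Support sources are kept separate (one linkage name, all
literature codes), and joint-support counting reports loci with linkage,
with literature, and with both. On the packaged table this gives 10
linkage-supported (12.5%), 20 literature-supported (25%), and 4 loci with
both kinds of evidence.

## Haplotype analysis and Duncan's multiple range test

Haplotypes use all polymorphic SNPs in the annotated gene span (an optional
filter restricts to marked coding SNPs). Accessions with any missing call
in the span are excluded (`missing`), heterozygous accessions likewise
(`heterozygous`): the panels are near-homozygous inbred rice, and exclusion
is conservative and auditable where imputation would be invention.
Haplotypes with fewer than `min_count` carriers (default 5) are dropped
(`rare`); the rest are named Hap1..HapN by descending carrier count, ties
by first occurrence.

Duncan's test: one-way ANOVA supplies MSE and error df; means are ranked;
a stretch of p adjacent ranked means is tested against the least
significant range

    R_p = q(γ_p; p, df) · sqrt(MSE / n_h),   γ_p = (1−α)^(p−1)

with `q` the studentized-range quantile (scipy's distribution function) and
`n_h` the harmonic mean of the two group sizes compared (Kramer
adjustment). The step-down rule applies: a stretch contained in a
non-significant stretch is never declared significant. Pairs separated
iff their spanning stretch is significant; because non-significant pairs
then form contiguous stretches, the compact letter display is the classical
underlining (one letter per maximal non-significant stretch).

Two properties pin the engine down: with two groups the procedure is
*exactly* the pooled-variance t test (`q(2, df) = √2·t(df)`), and under a
complete null with k groups the probability of any separation is the
full-range test's protection level `1 − (1−α)^(k−1)` — about 0.185 for
k = 5 at α = 0.05. That liberal per-experiment error is a defining,
intended property of Duncan's procedure, and the Monte-Carlo calibration
test asserts it (measured 0.177 ± 0.009 at 2,000 replicates).

Star levels run the test at α = 0.05, 0.01, 0.001, 0.0001; the star is the
most stringent α with at least one separated pair (`ns` otherwise). Some
published tables print a five-asterisk glyph for the fourth level; it is
normalized to four stars here, matching the four listed alphas.

Favorable-haplotype classification (at the `*` level, Fe/Zn/Cd):

* **favorable** — significantly higher than ≥1 other haplotype in Fe or
  Zn, not significantly lower in either micronutrient, not significantly
  higher in Cd;
* **conditional** — a micronutrient gain accompanied by a significant loss
  in the other micronutrient or a significant Cd increase;
* **unfavorable** — micronutrient loss or Cd gain with no micronutrient
  gain;
* **neutral** — otherwise.

This codifies the breeding narrative: the flagship pattern (higher Fe and
Zn, Cd unaffected) is favorable; a gain traded against a loss is a
second-choice, conditional haplotype.

## Synthetic panel generator

The generator emulates a 698-accession two-subset panel (defaults: 265 X +
433 G accessions, 12 chromosomes). Allele frequencies diverge between
subsets around shared ancestral frequencies (Uniform(0.05, 0.95)) under a
Balding–Nichols model with divergence parameter F (default 0.15, which
gives clean PC1 separation of the subsets). SNPs come in blocks (default
10 SNPs): each subset draws a small pool of founder block-haplotypes
(default 6) from its frequencies, and each accession copies one founder
with a per-SNP escape probability (default 0.02) — a cheap LD device that
yields genes with few distinct haplotypes, which the haplotype stage needs.
Dosages are homozygous (0/2) by default, matching inbred rice; residual
heterozygosity and missingness are config knobs defaulting to 0.

Phenotype = per-subset baseline + planted causal-haplotype increments +
Gaussian noise, floored at a small positive value (concentrations are
non-negative). Default baselines (ppm) target the pooled panel statistics:
Fe 2.4 (both subsets), Zn 14.8/17.4 (X/G; pooled 16.4), Cd 0.0175/0.0038
(pooled 0.009 — the strong subset offset makes the pooled Cd distribution
bimodal with the G mode lower, and gives Cd loci extra power in pooled
scans), Mn 9.7, Cu 2.90/3.38 (pooled 3.2), Se 0.040 with overlapping
subsets. Causal genes add fixed ppm increments per realized haplotype,
ranked by frequency. One integer seed drives everything through spawned
substreams; identical config + seed is bit-identical.

What the generator does **not** model: realistic demography or coalescent
LD decay, skewed trait distributions (real mineral concentrations are
right-skewed; the generator is Gaussian within subset), genotype error,
soil/environment effects, and genotype-by-environment interaction. Passing
tests therefore demonstrate correctness of the *machinery* under a clean,
structured null — not field-data performance. No published heritability
exists for these traits; simulated heritability is whatever the planted
effects produce and is reported in `SimulationTruth`, not claimed.

## Problem sizes and numerics

The test suite and acceptance script run desk-scale versions of every
analysis: null panels of 240–500 accessions and 800–6,000 SNPs, 10–20
replicate power/calibration studies, 2,000-replicate Duncan Monte-Carlo,
and a full demo pipeline of 300 accessions × 5,000 SNPs with three planted
causal genes. Studentized-range quantiles are cached per (p, df, α).
Kinship eigendecompositions are computed once and shared across traits.
Degenerate inputs (all-monomorphic genotypes, empty association tables,
empty groups, flat REML profiles, zero-length files) return typed errors
or flagged empty results rather than NaNs.

## Known limitations

* GAPIT-style *compressed* MLM (clustering individuals into groups) is not
  implemented; plain MLM with P3D is the statistical limit of compression
  at group count = n, and compression is primarily a speed device.
* The shared-marker utility intersects on position + allele identity; the
  matching rule used to build the original cross-subset marker set was
  never published.
* Literature-support annotation consumes a user-supplied interval table;
  no automated liftover or literature mining.
* Haplotype analysis is unphased by construction (homozygous panel);
  heterozygous accessions are excluded, not phased.
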