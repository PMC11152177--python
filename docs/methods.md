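# Methods

## Scope and model

`holovar` decomposes the variance of a quantitative trait measured on a
cohort that has both genome-wide genotypes and gut 16S (ASV-level)
profiles. The linear mixed model is

    y = X c + u + e,    u ~ N(0, σ²_k K),   e ~ N(0, σ²_e I),

where K is a similarity kernel among individuals and X holds fixed
covariates (intercept, batch indicators, optionally genetic principal
components and extra numeric covariates). With K the genomic relationship
matrix (GRM) the ratio σ²_k/(σ²_k+σ²_e) is the SNP heritability h²; with K
the microbial relationship matrix (MRM) it is the microbiability m². Both
kernels are cross-product kernels of column-standardized features (dosages
standardized by √(2p̄(1−p̄)) under Hardy–Weinberg; abundances by their
population standard deviation), so each has average diagonal 1 and the two
ratios are directly comparable.

Downstream stages reuse the same machinery: single-SNP mixed-model
association, eigenvalue-based effective-test thresholds, cis/trans eQTL
windows around transcription start sites, the SMR instrument test combining
eQTL and GWAS summary statistics, and a detection-rate-stratified
correlation screen for individual taxa.

## REML estimation

The variance ratio is estimated by exact profile REML rather than iterative
average-information updates. With Q₂ an orthonormal basis of the complement
of col(X), the rotated kernel Q₂ᵀKQ₂ is eigendecomposed once
(eigenvalues d_i, rotated data w_i), and the restricted log-likelihood at
ratio h with the total variance profiled out is

    ℓ(h) = −½ [ m log(2π σ̂²(h)) + Σ log v_i + m ],
    v_i = h d_i + (1 − h),   σ̂²(h) = (1/m) Σ w_i²/v_i,   m = n − p.

ℓ is maximized on [0, 1] by bounded scalar search (xatol 1e-10), with the
endpoints evaluated explicitly since bounded Brent cannot land on them.
Rationale: at desk scale (n up to a few thousand) one n×n eigendecomposition
is cheap, the profile likelihood in one parameter cannot diverge, and a grid
search over the same likelihood provides a natural independent oracle (the
test suite checks agreement within 0.002 on random instances).

Numerical choices:

* **Boundary estimates.** Ratios within 1e-6 of 0 or 1 are returned as
  legitimate optima with a `boundary` flag; variance components are clamped
  nonnegative by the parametrization itself.
* **Standard error.** From the numerical second derivative (central
  difference, step 1e-4) of the profile likelihood at the optimum; NaN at
  boundaries where curvature is one-sided.
* **Identifiability.** If the projected kernel is a multiple of the
  identity (eigenvalue spread below 1e-10 relative), kernel and residual
  variance are confounded and the fit raises an error rather than returning
  an arbitrary ratio. The GWAS catches this case and degenerates to
  ordinary least squares, which is the correct limit.

The permutation null reorders phenotype rows (jointly with their covariate
rows) against the fixed kernel, refits, and reports the one-sided add-one
p-value (1 + #{permuted ≥ observed})/(n_perm + 1), which can never be 0.
Failed permutation fits would be excluded with a warning; in practice the
profile fit cannot fail to converge.

## GWAS

The null variance components are estimated once and reused for every SNP:
after whitening by V^{−1/2} the per-SNP fit is ordinary least squares, so
the whole scan is vectorized. The per-SNP likelihood-ratio statistic is
n·log(RSS₀/RSS₁) (residual scale profiled at fixed variance ratio),
referred to χ²₁; a Wald t-test with n−p−1 degrees of freedom is reported
alongside and is exactly OLS when the kernel is the identity. Exact per-SNP
re-estimation of the variance ratio is available behind a flag; at the
sample sizes this package targets the difference is negligible.

The effective number of tests follows the eigenvalue method: per block of
consecutive SNPs (default 1000), count the minimal number of leading
eigenvalues of the dosage correlation matrix whose cumulative sum reaches
c = 0.995 of the total, and sum over blocks. These defaults are the
original convention for the method; both are configurable. Zero-variance
SNPs carry no test and contribute nothing. Thresholds are α/M_eff
(genome-wide) and 1/M_eff (suggestive).

## Expression and eQTL/SMR

Counts are filtered on TPM ≥ 0.1 and raw reads ≥ 6 in ≥ 20% of samples,
then scaled between samples by trimmed-mean-of-M factors (reference sample:
upper-quartile fraction closest to the mean; 30% rank-trim on M, 5% on A;
precision-weighted mean of surviving M; factors normalized to geometric
mean 1). Regressions use per-gene standardized log2 counts-per-million
(TMM-scaled, +1 pseudocount). Hidden expression structure is absorbed by
top expression principal components used as covariates (default 3) — a
deliberate replacement for probabilistic residual-factor software, which
would add a heavy dependency for the same role at this scale.

cis windows are TSS ± 1 Mb inclusive; trans pairs are on another chromosome
or beyond TSS ± 5 Mb with MAF > 5%. The two sets are disjoint by
construction, and variants falling between the window and the exclusion
zone are deliberately tested in neither mode. Gene-level cis significance
uses direct permutations of the expression vector (default 200, add-one
rule) rather than a fitted extreme-value approximation — transparent, and
cheap at desk scale. The SMR statistic for instrument z_e and trait
association z_g is T = z_e²z_g²/(z_e²+z_g²) on χ²₁, with effect
b_xy = b_gwas/b_eqtl; T is bounded by min(z_e², z_g²) and tends to z_g² as
the instrument strengthens. BH-FDR is applied over the genes tested.

## Microbe associations

Taxa are stratified by detection rate: ≥ 60% detected — quantitative with
zeros recoded to missing (an undetected core taxon is treated as escaping
detection); 30–60% — presence/absence; < 30% — excluded. Correlations are
Spearman by default; a Pearson policy for the high-detection stratum is
provided because both conventions are in use depending on the phenotype
class. A correlation is reported only with ≥ 10 complete pairs (a package
choice; below that the estimate is noise), and degenerate codings are
flagged rather than tested. BH-FDR families are per taxonomic level.
Alpha diversity is Shannon (natural log) and Gini–Simpson (1 − Σp²) on
rows renormalized over the retained taxa.

## Synthetic cohorts

The generator provides the statistical structure the estimators assume:

* **Genotypes.** Two latent Gaussian haplotypes per individual, AR(1)
  within blocks (correlation `ld_rho`, default block 100 SNPs), thresholded
  at the normal quantile of a per-SNP MAF drawn uniformly from `maf_range`
  (default [0.05, 0.5]). This yields Hardy–Weinberg dosages with tunable
  LD; it does not reproduce real LD maps, recombination hotspots, or allele
  frequency spectra.
* **Microbiome.** Taxa partitioned by a detection profile — default 30%
  of taxa detected in ~90% of samples, 40% in ~50%, 30% in ~20%, the
  core/intermediate/sporadic shape typical of gut ASV tables — with
  log-normal abundance given presence and rows closed to sum 1.
  Compositional closure induces the usual weak negative dependence among
  taxa; no phylogenetic or ecological interaction structure is modeled.
* **Phenotype.** Gaussian effects on a configurable number of causal SNPs
  (default 200) and taxa (default 50), with the genetic and microbial
  component sample variances rescaled exactly to `h2_true` and `m2_true`
  on the unit-variance (g+m+e) scale; batch shifts (default 4 levels,
  SD 0.5) sit on top and are meant to be absorbed by covariates. The
  bundle records the realized fractions, which are the recovery targets.
  The ordinal 3-level grade is the tertile coding of the latent trait;
  both latent and ordinal traits are exposed since either convention can
  be analyzed.
* **Expression.** Gamma–Poisson counts around exp(baseline + effect ×
  standardized dosage) with planted cis/trans effects and configurable
  dispersion.

One master seed spawns independent child streams per table
(`numpy.random.SeedSequence`), so bundles are bit-identical given the
config and individually reproducible per table.

What passing recovery tests shows — and does not. The generator satisfies
the mixed model's assumptions by construction (Gaussian effects, no
gene–environment interaction, microbiome independent of genotype unless
both fractions are set). Recovery of h² and m² under these conditions
validates the estimator implementations, not the biological
identifiability of the decomposition in real data, where diet, cage, and
host–microbiome covariance can confound the kernels.

## Problem sizes

The standard recovery protocol uses 30 replicate cohorts of n = 600 with
2,000 SNPs (200 causal) for h² and 300 ASVs (50 causal) for m², and a
permutation null of 200 reorderings at n = 500 — sizes at which the
Monte-Carlo standard error of a 30-replicate mean ratio is about 0.01,
comfortably inside the ±0.05 recovery band, while a full run stays under a
minute on one CPU.

## Known limitations

* Single-kernel fits only in the default path; the h²+m² joint model is not
  fitted simultaneously (matching the convention of correcting genetics via
  principal components when estimating m²).
* The ordinal grade is analyzed as a quantitative trait if passed to the
  estimators; no threshold/liability model is provided.
* The trans-eQTL scan reports nominal p-values only.
* No HEIDI-style heterogeneity test accompanies SMR; a significant T says
  "association consistent with mediation," not "mediation proven."
* Sparse-GRM support is a thresholding of the dense GRM; no algorithmic
  exploitation of sparsity is attempted at these sample sizes.
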