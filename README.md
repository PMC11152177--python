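# holovar

Hologenomic variance decomposition for quantitative traits: how much of a
phenotype — for example hepatic steatosis in laying hens — is explained by
host genetics, and how much by the gut microbial community? `holovar`
implements the full desk-scale analysis chain: relationship-matrix
construction, REML variance components with a permutation null, mixed-model
GWAS with effective-test thresholds, cis/trans eQTL mapping with
summary-based Mendelian randomization, and detection-rate-stratified
microbe–phenotype association — together with a synthetic-cohort generator
so every stage runs and is testable without any external data.

## Models

**Kernels.** The genomic relationship matrix over N SNPs is

    g_ij = (1/N) Σ_v (x_iv − 2p̄_v)(x_jv − 2p̄_v) / (2p̄_v(1 − p̄_v))

with x the allele dosage and p̄_v the observed allele frequency. The
microbial relationship matrix is the analogous kernel over per-taxon
standardized relative abundances, m_ij = (1/N_s) Σ_a z_ia z_ja, with
population-variance standardization so trace(MRM)/n = 1 exactly.

**Variance components.** The trait model is y = Xc + u + e with
u ~ N(0, σ²_k K); the estimand is the ratio σ²_k/(σ²_k + σ²_e) — the SNP
heritability h² when K is the GRM, the microbiability m² when K is the MRM.
The fit is exact profile REML: one rotation into the covariate-orthogonal
space, total variance profiled out analytically, and a bounded scalar search
over the ratio on [0, 1]. A permutation test (phenotypes reordered against
the fixed kernel) gives a null reference distribution for m².

**Association.** GWAS uses the mixed model y = Wα + xβ + u + ε with the
null variance components reused per SNP; p-values come from the
likelihood-ratio test (Wald t also reported). Multiple testing uses the
eigenvalue-based effective number of tests M_eff, giving thresholds α/M_eff
(genome-wide) and 1/M_eff (suggestive). eQTLs are mapped within a TSS ± 1 Mb
cis window (gene-level permutation empirical p) and beyond a TSS ± 5 Mb
exclusion for trans; the SMR statistic
T = z_e²z_g²/(z_e² + z_g²) tests whether expression mediates a trait
association using the top eQTL as instrument. Microbe–phenotype association
stratifies taxa by detection rate (≥60% quantitative with zeros as missing,
30–60% presence/absence, <30% excluded) with BH-FDR per taxonomic level.

## Worked example

```python
from holovar import (SimConfig, simulate_cohort, build_grm, build_mrm,
                     build_covariates, estimate_h2, estimate_m2, permute_m2)
from holovar.relatedness import genetic_pcs

bundle = simulate_cohort(SimConfig(
    n_individuals=600, n_snps=1500, n_asvs=300,
    h2_true=0.25, m2_true=0.26, seed=14))
grm, mrm = build_grm(bundle.genotypes), build_mrm(bundle.abundances)
pcs, _ = genetic_pcs(bundle.genotypes, 5)
h2 = estimate_h2(bundle.phenotypes, grm)
m2 = estimate_m2(bundle.phenotypes, mrm, pcs=pcs)
```

Running `python examples/02_heritability_microbiability.py` prints:

```
h2 = 0.251 (se 0.084), truth 0.245
m2 = 0.286 (se 0.051), truth 0.254
permutation null: mean permuted m2 = 0.020, p = 0.0050
```

The REML estimates recover the realized variance fractions of the generated
cohort within their standard errors, and the permutation null shows that a
kernel uncoupled from the phenotype yields only a ~2% apparent
microbiability — the observed m² is real signal, not kernel dimensionality.
The other scripts in `examples/` walk through the GWAS thresholds, the
eQTL + SMR causal-chain test, and the stratified microbe associations in the
same style.

A thin CLI mirrors the library (`holovar simulate | qc | grm | mrm | reml |
permute | gwas | meff | eqtl | smr | micro-assoc | run`); `holovar run
--config cfg.yaml` executes the full pipeline and writes a manifest with
per-stage checksums.

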