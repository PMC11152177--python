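"""Synthetic cohort generator.

Produces genotype, microbiome, phenotype, and expression tables with the
statistical structure the downstream variance-decomposition analysis assumes:

* diploid dosages from a Gaussian-copula haplotype model with per-block AR(1)
  linkage disequilibrium, thresholded at per-SNP minor-allele-frequency
  quantiles (Hardy-Weinberg by construction);
* zero-inflated compositional taxon abundances with a configurable
  detection-rate profile and log-normal abundance on the detected entries;
* a quantitative trait built as batch effects + polygenic + microbial +
  Gaussian residual at configured variance fractions, plus an ordinal
  3-level grade obtained by tertile-thresholding the latent trait;
* expression counts with planted cis/trans eQTL effects.

One master seed drives everything: child streams are spawned per table via
``numpy.random.SeedSequence`` so tables are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, AlignmentError, GenotypeMatrix, check_aligned

DEFAULT_DETECTION_PROFILE: list[tuple[float, float]] = [
    (0.30, 0.90),
    (0.40, 0.50),
    (0.30, 0.20),
]
"""Default zero-inflation profile: a core of near-ubiquitous taxa, a middle
tier detected in about half the cohort, and a sporadic tail — the shape
typical of gut 16S ASV tables."""


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort."""

    n_individuals: int = 600
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    block_size: int = 100
    n_asvs: int = 300
    detection_profile: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_DETECTION_PROFILE)
    )
    h2_true: float = 0.25
    m2_true: float = 0.0
    n_causal_snps: int = 200
    n_causal_taxa: int = 50
    batch_levels: int = 4
    batch_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.h2_true <= 1 and 0 <= self.m2_true <= 1):
            raise ValueError("variance fractions must be in [0, 1]")
        if self.h2_true + self.m2_true > 1:
            raise ValueError("h2_true + m2_true must not exceed 1")
        fracs = [f for f, _ in self.detection_profile]
        rates = [r for _, r in self.detection_profile]
        if not self.detection_profile or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("detection profile taxon fractions must sum to 1")
        if any(not (0 < r <= 1) for r in rates):
            raise ValueError("detection rates must be in (0, 1]")


@dataclass
class CohortTruths:
    """Ground truth of a simulated cohort: what the estimators should recover."""

    h2_realized: float
    m2_realized: float
    causal_snp_idx: np.ndarray
    snp_effects: np.ndarray
    causal_taxon_idx: np.ndarray
    taxon_effects: np.ndarray


@dataclass
class CohortBundle:
    genotypes: GenotypeMatrix
    abundances: AbundanceTable
    phenotypes: pd.DataFrame  # columns: sample_id, trait, grade, batch
    truths: CohortTruths


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-table stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    block_size: int = 100,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate an n x m dosage matrix with block-AR(1) LD.

    Each of the two haplotypes of each individual is an independent latent
    Gaussian AR(1) chain within a block (correlation ``ld_rho`` between
    adjacent SNPs, blocks independent); an allele is called alternate when
    its latent value falls below the normal quantile of the SNP's MAF, so
    per-SNP allele frequencies match the drawn MAF and genotypes are in
    Hardy-Weinberg proportions.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    rng = _child_rng(seed, 0)
    maf = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(maf)  # latent < thresh -> alternate allele

    def haplotype_latents() -> np.ndarray:
        z = rng.standard_normal((n, m))
        if ld_rho > 0:
            rt = np.sqrt(1 - ld_rho**2)
            for j in range(1, m):
                if j % block_size == 0:
                    continue  # block boundary: restart the chain
                z[:, j] = ld_rho * z[:, j - 1] + rt * z[:, j]
        return z

    h1 = (haplotype_latents() < thresh).astype(np.int8)
    h2 = (haplotype_latents() < thresh).astype(np.int8)
    dosages = (h1 + h2).astype(np.int16)

    meta = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "id": [f"snp{j + 1}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    sample_ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variant_meta=meta, sample_ids=sample_ids)


def simulate_microbiome(
    n: int,
    k: int,
    detection_profile: list[tuple[float, float]] | None = None,
    overdispersion: float = 1.0,
    seed: int = 0,
) -> AbundanceTable:
    """Simulate a samples x taxa relative-abundance table.

    Taxa are partitioned by the detection profile (fraction of taxa, target
    detection rate); presence is Bernoulli per sample and abundance given
    presence is log-normal with a taxon-specific baseline, then each row is
    closed to sum 1 over its detected taxa.
    """
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 samples and k >= 1 taxa")
    profile = detection_profile if detection_profile is not None else list(DEFAULT_DETECTION_PROFILE)
    if not profile:
        raise ValueError("detection profile must not be empty")
    fracs = np.array([f for f, _ in profile], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("detection profile taxon fractions must sum to 1")
    rng = _child_rng(seed, 1)

    counts = np.floor(np.cumsum(fracs) * k + 0.5).astype(int)
    counts = np.diff(np.concatenate([[0], counts]))
    counts[-1] += k - counts.sum()
    rates = np.repeat([r for _, r in profile], counts)

    baseline = rng.normal(0.0, 1.0, size=k)  # taxon-specific log-abundance level
    present = rng.random((n, k)) < rates
    logab = baseline + overdispersion * rng.standard_normal((n, k))
    raw = np.where(present, np.exp(logab), 0.0)
    # guarantee at least one detected taxon per row so closure is defined
    empty = ~present.any(axis=1)
    if empty.any():
        j = rng.integers(0, k, size=int(empty.sum()))
        raw[np.where(empty)[0], j] = np.exp(baseline[j])
    rel = raw / raw.sum(axis=1, keepdims=True)

    meta = pd.DataFrame(
        {
            "taxon_id": [f"asv{a + 1}" for a in range(k)],
            "level": ["ASV"] * k,
            "detection_rate": (rel > 0).mean(axis=0),
        }
    )
    sample_ids = [f"ind{i + 1}" for i in range(n)]
    return AbundanceTable(rel_abundance=rel, taxon_meta=meta, sample_ids=sample_ids)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _scale_to_var(component: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a component so its sample variance equals target_var exactly."""
    v = component.var()
    if target_var == 0 or v == 0:
        return np.zeros_like(component)
    return component * np.sqrt(target_var / v)


def simulate_phenotype(G: GenotypeMatrix, A: AbundanceTable, cfg: SimConfig) -> CohortBundle:
    """Build the latent trait and ordinal grade on top of genotypes + microbiome.

    trait = batch effect + genetic component + microbial component + residual,
    where the genetic and microbial components are Gaussian-effect sums over
    standardized causal columns, rescaled so their realized sample variances
    equal ``h2_true`` and ``m2_true`` on the unit-variance (g + m + e) scale.
    Batch shifts sit on top and are meant to be absorbed by fixed covariates.
    The ordinal grade is the tertile coding {0,1,2} of the latent trait.
    """
    check_aligned(G.sample_ids, A.sample_ids, "genotypes vs abundances")
    rng = _child_rng(cfg.seed, 2)
    n = G.n_samples

    n_causal_g = min(cfg.n_causal_snps, G.n_variants)
    causal_g = np.sort(rng.choice(G.n_variants, size=n_causal_g, replace=False))
    beta_g = rng.standard_normal(n_causal_g)
    g = _scale_to_var(_standardize(G.imputed()[:, causal_g]) @ beta_g, cfg.h2_true)

    n_causal_m = min(cfg.n_causal_taxa, A.n_taxa)
    causal_m = np.sort(rng.choice(A.n_taxa, size=n_causal_m, replace=False))
    beta_m = rng.standard_normal(n_causal_m)
    mcomp = _scale_to_var(_standardize(A.rel_abundance[:, causal_m]) @ beta_m, cfg.m2_true)

    resid = _scale_to_var(rng.standard_normal(n), 1.0 - cfg.h2_true - cfg.m2_true)

    batch = rng.integers(0, cfg.batch_levels, size=n)
    batch_effects = rng.normal(0.0, cfg.batch_sd, size=cfg.batch_levels)

    y = batch_effects[batch] + g + mcomp + resid
    var_y = (g + mcomp + resid).var()  # variance net of fixed effects
    truths = CohortTruths(
        h2_realized=float(g.var() / var_y),
        m2_realized=float(mcomp.var() / var_y),
        causal_snp_idx=causal_g,
        snp_effects=beta_g,
        causal_taxon_idx=causal_m,
        taxon_effects=beta_m,
    )

    q = np.quantile(y, [1 / 3, 2 / 3])
    grade = np.digitize(y, q).astype(int)

    phenotypes = pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "trait": y,
            "grade": grade,
            "batch": [f"b{b}" for b in batch],
        }
    )
    return CohortBundle(genotypes=G, abundances=A, phenotypes=phenotypes, truths=truths)


def simulate_cohort(cfg: SimConfig) -> CohortBundle:
    """Convenience wrapper: genotypes + microbiome + phenotype from one config."""
    G = simulate_genotypes(
        cfg.n_individuals,
        cfg.n_snps,
        cfg.maf_range,
        cfg.ld_rho,
        cfg.block_size,
        seed=cfg.seed,
    )
    A = simulate_microbiome(
        cfg.n_individuals, cfg.n_asvs, cfg.detection_profile, seed=cfg.seed
    )
    return simulate_phenotype(G, A, cfg)


def simulate_expression(
    G: GenotypeMatrix,
    gene_annotation: pd.DataFrame,
    eqtl_plan: list[tuple[str, str, float, str]],
    seed: int = 0,
    baseline_log_mean: float = 4.0,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate expression counts with planted eQTL effects.

    gene_annotation needs columns gene_id, chrom, tss (1-based) and
    optionally length (bp; defaults to 1000). eqtl_plan entries are
    (gene_id, variant_id, effect on the log scale per dosage SD, "cis"/"trans").
    Counts are gamma-Poisson (negative-binomial-like) around
    exp(baseline + effect * standardized dosage).

    Returns (counts DataFrame genes x samples, gene lengths Series).
    """
    rng = _child_rng(seed, 3)
    genes = list(gene_annotation["gene_id"])
    gene_pos = {g: i for i, g in enumerate(genes)}
    var_pos = {v: j for j, v in enumerate(G.variant_meta["id"])}
    n, n_genes = G.n_samples, len(genes)

    log_mu = np.tile(
        baseline_log_mean + rng.normal(0.0, 0.3, size=n_genes), (n, 1)
    )
    zdos = _standardize(G.imputed())
    for gene, variant, effect, _mode in eqtl_plan:
        if gene not in gene_pos:
            raise KeyError(f"unknown gene in eQTL plan: {gene}")
        if variant not in var_pos:
            raise KeyError(f"unknown variant in eQTL plan: {variant}")
        log_mu[:, gene_pos[gene]] += effect * zdos[:, var_pos[variant]]

    mu = np.exp(log_mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    if "length" in gene_annotation.columns:
        lengths = pd.Series(
            np.asarray(gene_annotation["length"], dtype=float), index=genes, name="length"
        )
    else:
        lengths = pd.Series(1000.0, index=genes, name="length")
    counts_df = pd.DataFrame(counts.T, index=genes, columns=G.sample_ids)
    return counts_df, lengths
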