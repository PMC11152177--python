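"""Quality-control filters and relationship-matrix construction.

The genomic relationship matrix (GRM) between individuals i and j is

    g_ij = (1/N) * sum_v (x_iv - 2 p̄_v)(x_jv - 2 p̄_v) / (2 p̄_v (1 - p̄_v))

over the N retained SNPs, where x is alternate-allele dosage and p̄_v the
observed alternate-allele frequency (the GRM is invariant to flipping which
allele is counted). The microbial relationship matrix (MRM) is the analogous
kernel on per-taxon standardized relative abundances,

    m_ij = (1/N_s) * sum_a z_ia z_ja,   z = (x - x̄) / sigma,

with population (1/n) variance so that trace(MRM)/n == 1 exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    MISSING,
    AbundanceTable,
    DegenerateInputError,
    GenotypeMatrix,
    RelationshipMatrix,
)

log = logging.getLogger(__name__)


def filter_genotypes(
    G: GenotypeMatrix,
    sample_call_rate: float = 0.9,
    snp_call_rate: float = 0.9,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Apply sample and SNP filters (samples first, PLINK convention).

    Samples with call rate <= sample_call_rate are removed, then SNPs are
    kept only if call rate > snp_call_rate AND minor allele frequency >
    maf_min, with frequencies recomputed on the surviving samples.
    """
    for t in (sample_call_rate, snp_call_rate, maf_min):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must be in [0, 1]")
    keep_s = G.call_rate(axis=1) > sample_call_rate
    if not keep_s.any():
        raise DegenerateInputError(
            f"all {G.n_samples} samples fail call rate > {sample_call_rate}"
        )
    d = G.dosages[keep_s]
    sample_ids = [s for s, k in zip(G.sample_ids, keep_s) if k]

    nonmiss = d != MISSING
    call = nonmiss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(
            nonmiss.sum(axis=0) > 0,
            np.where(d == MISSING, 0, d).sum(axis=0) / np.maximum(2 * nonmiss.sum(axis=0), 1),
            np.nan,
        )
    maf = np.minimum(p, 1 - p)
    keep_v = (call > snp_call_rate) & (maf > maf_min)
    log.info(
        "filter_genotypes: removed %d/%d samples (call rate <= %.3g), then "
        "%d/%d SNPs (call rate <= %.3g or MAF <= %.3g)",
        int((~keep_s).sum()), G.n_samples, sample_call_rate,
        int((~keep_v).sum()), G.n_variants, snp_call_rate, maf_min,
    )
    return GenotypeMatrix(
        dosages=d[:, keep_v],
        variant_meta=G.variant_meta.loc[keep_v].reset_index(drop=True),
        sample_ids=sample_ids,
    )


def filter_asvs(
    A: AbundanceTable,
    min_sample_fraction: float = 0.01,
    min_mean_abundance: float = 1e-6,
) -> AbundanceTable:
    """Drop taxa detected in < min_sample_fraction of samples or with mean
    relative abundance < min_mean_abundance.

    Rows are NOT re-closed to 1: the surviving taxa keep their original
    relative scale so downstream detection-rate strata stay comparable.
    """
    if min_sample_fraction < 0 or min_mean_abundance < 0:
        raise ValueError("thresholds must be >= 0")
    det = A.detection_rates()
    mean_ab = A.rel_abundance.mean(axis=0)
    keep = (det >= min_sample_fraction) & (mean_ab >= min_mean_abundance)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_asvs: removed %d/%d taxa", n_drop, A.n_taxa)
    if not keep.any():
        log.warning("filter_asvs: no taxa survive the filters")
    return AbundanceTable(
        rel_abundance=A.rel_abundance[:, keep],
        taxon_meta=A.taxon_meta.loc[keep].reset_index(drop=True),
        sample_ids=list(A.sample_ids),
    )


def build_grm(G: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from standardized dosages.

    Missing dosages are mean-imputed to 2*p̄_v before centering (so they
    contribute zero to the cross-products). Monomorphic SNPs are excluded
    with a warning; if nothing remains the input is degenerate.
    """
    p = G.alt_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateInputError("all SNPs monomorphic; GRM undefined")
    if (~poly).sum():
        log.warning("build_grm: excluding %d monomorphic SNPs", int((~poly).sum()))
    x = G.imputed()[:, poly]
    pv = p[poly]
    z = (x - 2 * pv) / np.sqrt(2 * pv * (1 - pv))
    k = (z @ z.T) / poly.sum()
    k = (k + k.T) / 2.0  # enforce exact symmetry against float round-off
    return RelationshipMatrix(values=k, sample_ids=list(G.sample_ids), kind="GRM")


def sparsify_grm(K: RelationshipMatrix, cutoff: float = 0.05) -> RelationshipMatrix:
    """Zero out off-diagonal entries below the relatedness cutoff.

    This is the sparse-GRM construction used by fastGWA-style mixed models:
    pairs with estimated relatedness under the cutoff are treated as
    unrelated; the diagonal is always preserved.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    v = K.values.copy()
    off = ~np.eye(K.n, dtype=bool)
    v[off & (v < cutoff)] = 0.0
    return RelationshipMatrix(values=v, sample_ids=list(K.sample_ids), kind="sparse-GRM")


def build_mrm(A: AbundanceTable) -> RelationshipMatrix:
    """Microbial relationship matrix from standardized relative abundances.

    Uses population (1/n) variance in the per-taxon standardization, which
    forces mean(diagonal) == 1 exactly. Zero-variance taxa are excluded.
    """
    x = A.rel_abundance
    sd = x.std(axis=0)  # population sd (ddof=0)
    ok = sd > 0
    if not ok.any():
        raise DegenerateInputError("all taxa constant; MRM undefined")
    if (~ok).sum():
        log.warning("build_mrm: excluding %d zero-variance taxa", int((~ok).sum()))
    z = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    m = (z @ z.T) / ok.sum()
    m = (m + m.T) / 2.0
    return RelationshipMatrix(values=m, sample_ids=list(A.sample_ids), kind="MRM")


def genetic_pcs(G: GenotypeMatrix, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the standardized dosage matrix.

    Returns (coordinates n x k, variance-explained fractions length k).
    Sign convention: the largest-magnitude loading of each component is
    positive, so PCs are reproducible across runs and platforms.
    """
    if k >= G.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    p = G.alt_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateInputError("all SNPs monomorphic; PCs undefined")
    pv = p[poly]
    z = (G.imputed()[:, poly] - 2 * pv) / np.sqrt(2 * pv * (1 - pv))
    z = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    flip = np.sign(vt[np.arange(k), np.abs(vt[:k]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    var_explained = (s[:k] ** 2) / (s**2).sum()
    return coords, var_explained
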