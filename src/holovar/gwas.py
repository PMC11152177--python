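"""Mixed-model single-variant association and effective-test thresholds.

Per-SNP model: y = W a + x b + u + e, with u ~ N(0, sigma2_g K). The null
variance components are estimated once by REML and reused for every SNP
(EMMAX-style); after whitening by the null covariance the per-SNP fit is
ordinary generalized least squares, and the likelihood-ratio statistic is
2(ll_alt - ll_null) with the residual scale profiled at each fit, referred
to a chi-square with 1 df. A Wald t-test p-value is reported alongside: with
an identity kernel the whitening is trivial and the Wald p equals the
ordinary linear-regression p exactly.

The multiple-testing burden is reduced to an effective number of tests by
the eigenvalue method ("simpleM"): within blocks of consecutive SNPs, the
number of leading eigenvalues of the dosage correlation matrix needed to
reach a fixed fraction of the total variance is counted and summed over
blocks. Genome-wide and suggestive significance levels are alpha / M_eff
and 1 / M_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, RelationshipMatrix, check_aligned
from .varcomp import NonIdentifiableError, reml_fit


@dataclass
class ThresholdSet:
    m_eff: int
    genome_wide: float
    suggestive: float


def significance_thresholds(m_eff: int, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni-style thresholds on the effective number of tests."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return ThresholdSet(m_eff=int(m_eff), genome_wide=alpha / m_eff, suggestive=1.0 / m_eff)


def simple_m_eff(G: GenotypeMatrix, c: float = 0.995, block_size: int = 1000) -> int:
    """Effective number of independent tests by block-wise eigendecomposition.

    For each block of ``block_size`` consecutive SNPs, the dosage correlation
    matrix is eigendecomposed and the minimal count of leading eigenvalues
    whose cumulative sum reaches ``c`` of the total is taken; M_eff is the
    sum over blocks. Zero-variance SNPs carry no test and contribute 0.
    """
    if not (0 < c <= 1):
        raise ValueError("c must be in (0, 1]")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    x = G.imputed()
    m_eff = 0
    for start in range(0, G.n_variants, block_size):
        block = x[:, start : start + block_size]
        sd = block.std(axis=0)
        block = block[:, sd > 0]
        k = block.shape[1]
        if k == 0:
            continue
        if k == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0.0, None)
        cum = np.cumsum(ev) / ev.sum()
        m_eff += int(np.searchsorted(cum, c - 1e-12) + 1)
    return m_eff


def lmm_gwas(
    y: np.ndarray,
    W: np.ndarray,
    G: GenotypeMatrix,
    K: RelationshipMatrix,
    reestimate: bool = False,
) -> pd.DataFrame:
    """Mixed-model association scan over all SNPs.

    Parameters
    ----------
    y : trait vector (n,)
    W : covariate matrix (n, p) including the intercept
    G : genotypes (missing dosages are mean-imputed)
    K : random-effect kernel (GRM or sparse GRM), PSD
    reestimate : if True, refit the variance ratio per SNP with the SNP in
        the fixed effects (exact per-SNP REML); default reuses the null fit.

    Returns one row per SNP: id, chrom, pos, af, beta, se, lrt, p_value
    (likelihood-ratio), p_wald. Monomorphic SNPs get NaN statistics and a
    ``degenerate`` flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    check_aligned(G.sample_ids, K.sample_ids, "genotypes vs kernel")
    n, p = W.shape
    if y.size != n or G.n_samples != n:
        raise ValueError("y, W and G sample counts do not agree")

    try:
        null_ratio = reml_fit(y, W, K).ratio
    except NonIdentifiableError:
        # kernel proportional to identity: any ratio gives the same V up to
        # scale, and the model collapses to ordinary least squares
        null_ratio = 0.0
    d, u = np.linalg.eigh(K.values)
    d = np.clip(d, 0.0, None)

    def whiten(h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        wts = 1.0 / np.sqrt(np.maximum(h * d + (1.0 - h), 1e-12))
        ty = wts * (u.T @ y)
        tW = wts[:, None] * (u.T @ W)
        tX = wts[:, None] * (u.T @ G.imputed())
        return ty, tW, tX

    def scan(ty: np.ndarray, tW: np.ndarray, tx: np.ndarray) -> tuple[float, ...]:
        """GLS of one whitened SNP given whitened covariates; returns
        (beta, se, lrt, p_lrt, p_wald)."""
        q, _ = np.linalg.qr(tW)
        ry = ty - q @ (q.T @ ty)
        rx = tx - q @ (q.T @ tx)
        xtx = float(rx @ rx)
        if xtx <= 1e-12:
            return (np.nan,) * 5
        beta = float(rx @ ry) / xtx
        rss0 = float(ry @ ry)
        rss1 = rss0 - beta**2 * xtx
        dof = n - p - 1
        se = np.sqrt(max(rss1, 1e-300) / dof / xtx)
        tstat = beta / se
        p_wald = 2.0 * stats.t.sf(abs(tstat), dof)
        lrt = n * (np.log(rss0) - np.log(max(rss1, 1e-300)))
        p_lrt = stats.chi2.sf(lrt, 1)
        return beta, se, lrt, p_lrt, p_wald

    af = G.alt_freq()
    rows = []
    if not reestimate:
        ty, tW, tX = whiten(null_ratio)
        q, _ = np.linalg.qr(tW)
        ry = ty - q @ (q.T @ ty)
        rX = tX - q @ (q.T @ tX)
        xtx = np.einsum("ij,ij->j", rX, rX)
        xty = ry @ rX
        ok = xtx > 1e-12
        beta = np.where(ok, xty / np.where(ok, xtx, 1.0), np.nan)
        rss0 = float(ry @ ry)
        rss1 = np.maximum(rss0 - beta**2 * xtx, 1e-300)
        dof = n - p - 1
        se = np.sqrt(rss1 / dof / np.where(ok, xtx, 1.0))
        tstat = beta / se
        p_wald = 2.0 * stats.t.sf(np.abs(tstat), dof)
        lrt = n * (np.log(rss0) - np.log(rss1))
        p_lrt = stats.chi2.sf(lrt, 1)
        for j in range(G.n_variants):
            rows.append((beta[j], se[j], lrt[j], p_lrt[j], p_wald[j]) if ok[j] else (np.nan,) * 5)
    else:
        for j in range(G.n_variants):
            xj = G.imputed()[:, j]
            if xj.std() == 0:
                rows.append((np.nan,) * 5)
                continue
            alt = reml_fit(y, np.column_stack([W, xj]), K)
            ty, tW, tX = whiten(alt.ratio)
            rows.append(scan(ty, tW, tX[:, j]))

    out = pd.DataFrame(rows, columns=["beta", "se", "lrt", "p_value", "p_wald"])
    out.insert(0, "id", list(G.variant_meta["id"]))
    out.insert(1, "chrom", list(G.variant_meta["chrom"]))
    out.insert(2, "pos", list(G.variant_meta["pos"]))
    out.insert(3, "af", af)
    out["degenerate"] = out["beta"].isna()
    return out
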