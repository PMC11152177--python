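"""Expression preprocessing, cis/trans eQTL mapping, and the SMR test.

Expression is normalized within samples to transcripts per million (TPM) for
filtering, and between samples with trimmed-mean-of-M-values (TMM) scaling
factors. Regressions run on per-gene standardized log2 counts-per-million
(TMM-scaled, +1 pseudocount), optionally adjusted for covariates including
top expression principal components as hidden-factor surrogates.

cis associations are tested for all variants within a window around the
gene's transcription start site (inclusive boundaries) and summarized at the
gene level by a permutation empirical p-value of the minimum nominal p.
trans pairs are those on a different chromosome or beyond a larger exclusion
zone around the TSS, with a minor-allele-frequency floor; these get nominal
p-values only. Note the deliberate no-man's-land between the cis window and
the trans exclusion: a variant 1-5 Mb from the TSS is tested in neither mode.

The summary-data-based Mendelian randomization (SMR) statistic treats the
top eQTL as an instrument for gene expression on the trait:

    b_xy = b_gwas / b_eqtl,   T_smr = z_e^2 z_g^2 / (z_e^2 + z_g^2),

with p from a 1-df chi-square; T_smr is bounded by the weaker of the two
z-squares, so a gene can never look more causal than its instrument or its
trait association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with lengths; TPM and TMM factors attached."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    lengths: pd.Series  # bp, indexed by gene
    tpm: pd.DataFrame | None = None
    tmm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts closed to 1e6."""
    rpk = counts.div(lengths.reindex(counts.index) / 1e3, axis=0)
    return rpk.div(rpk.sum(axis=0), axis=1) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    Reference sample: the one whose upper-quartile count fraction is closest
    to the mean across samples. Per sample, M (log2 ratio of count
    fractions vs reference) and A (average log2 abundance) are computed over
    genes expressed in both; the top/bottom ``logratio_trim`` by M and
    ``abs_trim`` by A are discarded and the factor is 2 to the
    precision-weighted mean of the surviving M values. Factors are scaled to
    have geometric mean 1 across samples.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs nonzero library size")
    frac = x / lib
    uq = np.array([np.quantile(frac[:, j][x[:, j] > 0], 0.75) if (x[:, j] > 0).any() else 0
                   for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        both = (x[:, j] > 0) & (x[:, ref] > 0)
        yj, yr = x[both, j], x[both, ref]
        nj, nr = lib[j], lib[ref]
        m = np.log2((yj / nj) / (yr / nr))
        a = 0.5 * np.log2((yj / nj) * (yr / nr))
        if m.size == 0 or np.allclose(m, m[0]):
            factors[j] = 2.0 ** (m[0] if m.size else 0.0)
            continue
        mr = stats.rankdata(m) / m.size
        ar = stats.rankdata(a) / a.size
        keep = (
            (mr > logratio_trim) & (mr <= 1 - logratio_trim)
            & (ar > abs_trim) & (ar <= 1 - abs_trim)
        )
        if not keep.any():
            keep = np.ones_like(keep)
        w = 1.0 / ((nj - yj) / (nj * yj) + (nr - yr) / (nr * yr))  # delta-method precision
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def filter_normalize_expression(
    E: ExpressionMatrix,
    tpm_min: float = 0.1,
    read_min: int = 6,
    sample_fraction: float = 0.2,
) -> ExpressionMatrix:
    """Expression QC and normalization.

    Keeps genes with TPM >= tpm_min AND raw reads >= read_min in at least
    ``sample_fraction`` of samples; recomputes TPM on the surviving genes
    and attaches TMM between-sample factors.
    """
    tpm = compute_tpm(E.counts, E.lengths)
    ok = ((tpm >= tpm_min) & (E.counts >= read_min)).mean(axis=1) >= sample_fraction
    counts = E.counts.loc[ok]
    lengths = E.lengths.reindex(counts.index)
    return ExpressionMatrix(
        counts=counts,
        lengths=lengths,
        tpm=compute_tpm(counts, lengths),
        tmm_factors=tmm_factors(counts),
    )


def log_expression(E: ExpressionMatrix, standardize: bool = True) -> pd.DataFrame:
    """log2 TMM-scaled counts-per-million (+1), per-gene standardized."""
    f = E.tmm_factors if E.tmm_factors is not None else tmm_factors(E.counts)
    eff_lib = E.counts.sum(axis=0) * f
    logcpm = np.log2(E.counts.div(eff_lib, axis=1) * 1e6 + 1.0)
    if standardize:
        sd = logcpm.std(axis=1, ddof=0).replace(0, 1.0)
        logcpm = logcpm.sub(logcpm.mean(axis=1), axis=0).div(sd, axis=0)
    return logcpm


def expression_pcs(E: ExpressionMatrix, k: int = 3) -> np.ndarray:
    """Top-k sample-space principal components of log expression, used as
    hidden-factor covariates in eQTL regressions."""
    z = log_expression(E).to_numpy()
    z = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return (vt[:k] * s[:k, None]).T  # samples x k


def _residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None:
        return y - y.mean(axis=0)
    q, _ = np.linalg.qr(np.column_stack([np.ones(y.shape[0]), C]))
    return y - q @ (q.T @ y)


def _marginal_stats(ry: np.ndarray, rX: np.ndarray, dof: int):
    """Per-column OLS slope/SE/p of ry on each column of rX (both residualized)."""
    xtx = np.einsum("ij,ij->j", rX, rX)
    ok = xtx > 1e-12
    safe = np.where(ok, xtx, 1.0)
    beta = (ry @ rX) / safe
    rss = np.maximum(float(ry @ ry) - beta**2 * xtx, 1e-300)
    se = np.sqrt(rss / dof / safe)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return np.where(ok, beta, np.nan), np.where(ok, se, np.nan), np.where(ok, p, np.nan), ok


def map_cis_eqtl(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    tss: pd.DataFrame,
    window: int = 1_000_000,
    n_perm: int = 200,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """cis eQTL scan with per-gene permutation empirical p-values.

    ``tss`` needs columns gene_id, chrom, tss (1-based). For each annotated
    gene, all variants with |pos - TSS| <= window on the same chromosome are
    tested by linear regression of standardized log expression on dosage
    (covariate-adjusted). The gene-level empirical p compares the observed
    minimum nominal p with minima under permutations of the expression rows
    (add-one rule), which calibrates for the number and correlation of the
    variants in the window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    expr = log_expression(E)
    n = len(G.sample_ids)
    if list(expr.columns) != list(G.sample_ids):
        expr = expr.loc[:, G.sample_ids]
    dos = _residualize(G.imputed(), covariates)
    n_cov = 1 + (0 if covariates is None else np.atleast_2d(covariates).shape[1])
    dof = n - n_cov - 1
    tss_map = tss.set_index("gene_id")

    records = []
    for gene in expr.index:
        if gene not in tss_map.index:
            continue
        chrom, t0 = str(tss_map.loc[gene, "chrom"]), int(tss_map.loc[gene, "tss"])
        dist = G.variant_meta["pos"].to_numpy() - t0
        in_cis = (G.variant_meta["chrom"].astype(str).to_numpy() == chrom) & (
            np.abs(dist) <= window
        )
        idx = np.where(in_cis)[0]
        if idx.size == 0:
            continue
        ry = _residualize(expr.loc[gene].to_numpy(dtype=float), covariates)
        rX = dos[:, idx]
        beta, se, p, ok = _marginal_stats(ry, rX, dof)
        obs_min = np.nanmin(p) if np.isfinite(p).any() else np.nan
        if n_perm > 0 and np.isfinite(obs_min):
            hits = 0
            for _ in range(n_perm):
                yp = ry[rng.permutation(n)]
                _, _, pp, _ = _marginal_stats(yp, rX, dof)
                if np.nanmin(pp) <= obs_min:
                    hits += 1
            p_emp = (1.0 + hits) / (n_perm + 1.0)
        else:
            p_emp = np.nan
        for jj, j in enumerate(idx):
            records.append(
                dict(
                    gene_id=gene,
                    variant_id=G.variant_meta["id"].iloc[j],
                    distance=int(dist[j]),
                    mode="cis",
                    beta=beta[jj],
                    se=se[jj],
                    p_nominal=p[jj],
                    p_empirical=p_emp,
                )
            )
    return pd.DataFrame(
        records,
        columns=["gene_id", "variant_id", "distance", "mode", "beta", "se",
                 "p_nominal", "p_empirical"],
    )


def map_trans_eqtl(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    tss: pd.DataFrame,
    exclusion: int = 5_000_000,
    maf_min: float = 0.05,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """trans eQTL scan: nominal tests of gene x variant pairs on different
    chromosomes or beyond the TSS exclusion zone, with MAF > maf_min."""
    if exclusion <= 0:
        raise ValueError("exclusion must be positive")
    expr = log_expression(E)
    if list(expr.columns) != list(G.sample_ids):
        expr = expr.loc[:, G.sample_ids]
    p_v = G.alt_freq()
    maf = np.minimum(p_v, 1 - p_v)
    common = maf > maf_min
    dos = _residualize(G.imputed(), covariates)
    n = len(G.sample_ids)
    n_cov = 1 + (0 if covariates is None else np.atleast_2d(covariates).shape[1])
    dof = n - n_cov - 1
    tss_map = tss.set_index("gene_id")

    records = []
    vchrom = G.variant_meta["chrom"].astype(str).to_numpy()
    vpos = G.variant_meta["pos"].to_numpy()
    for gene in expr.index:
        if gene not in tss_map.index:
            continue
        chrom, t0 = str(tss_map.loc[gene, "chrom"]), int(tss_map.loc[gene, "tss"])
        dist = vpos - t0
        eligible = common & ((vchrom != chrom) | (np.abs(dist) > exclusion))
        idx = np.where(eligible)[0]
        if idx.size == 0:
            continue
        ry = _residualize(expr.loc[gene].to_numpy(dtype=float), covariates)
        beta, se, p, ok = _marginal_stats(ry, dos[:, idx], dof)
        for jj, j in enumerate(idx):
            records.append(
                dict(
                    gene_id=gene,
                    variant_id=G.variant_meta["id"].iloc[j],
                    distance=int(dist[j]) if vchrom[j] == chrom else None,
                    mode="trans",
                    beta=beta[jj],
                    se=se[jj],
                    p_nominal=p[jj],
                    p_empirical=np.nan,
                )
            )
    return pd.DataFrame(
        records,
        columns=["gene_id", "variant_id", "distance", "mode", "beta", "se",
                 "p_nominal", "p_empirical"],
    )


@dataclass
class SmrResult:
    b_xy: float
    t_smr: float
    p_smr: float
    flagged: bool = False  # instrument effect was zero; b_xy undefined


def smr_test(b_eqtl: float, se_eqtl: float, b_gwas: float, se_gwas: float) -> SmrResult:
    """Two-step instrumental-variable test from GWAS and eQTL summary data."""
    if se_eqtl <= 0 or se_gwas <= 0:
        raise ValueError("standard errors must be positive")
    z_e = b_eqtl / se_eqtl
    z_g = b_gwas / se_gwas
    denom = z_e**2 + z_g**2
    t_smr = 0.0 if denom == 0 else (z_e**2 * z_g**2) / denom
    p_smr = float(stats.chi2.sf(t_smr, 1))
    if b_eqtl == 0:
        return SmrResult(b_xy=float("nan"), t_smr=t_smr, p_smr=p_smr, flagged=True)
    return SmrResult(b_xy=b_gwas / b_eqtl, t_smr=t_smr, p_smr=p_smr)


def smr_batch(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """SMR over the top eQTL per gene, joined to GWAS summary stats by
    variant id, with BH-FDR over the tested genes.

    ``gwas`` columns: id, beta, se. ``eqtl`` columns: gene_id, variant_id,
    beta, se, p_nominal.
    """
    top = (
        eqtl.dropna(subset=["p_nominal"])
        .sort_values("p_nominal")
        .groupby("gene_id", sort=False)
        .head(1)
    )
    merged = top.merge(
        gwas[["id", "beta", "se"]].rename(
            columns={"id": "variant_id", "beta": "b_gwas", "se": "se_gwas"}
        ),
        on="variant_id",
        how="inner",
    )
    results = [
        smr_test(r.beta, r.se, r.b_gwas, r.se_gwas) for r in merged.itertuples()
    ]
    out = merged[["gene_id", "variant_id"]].copy()
    out["b_eqtl"] = merged["beta"].to_numpy()
    out["b_gwas"] = merged["b_gwas"].to_numpy()
    out["b_xy"] = [r.b_xy for r in results]
    out["t_smr"] = [r.t_smr for r in results]
    out["p_smr"] = [r.p_smr for r in results]
    out["q_smr"] = bh_fdr(out["p_smr"].to_numpy()) if len(out) else []
    out["significant"] = out["q_smr"] < fdr if len(out) else []
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
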