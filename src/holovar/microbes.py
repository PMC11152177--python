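"""Alpha diversity and detection-rate-stratified taxon-phenotype association.

Zero-inflated relative abundances make a single correlation estimator
untrustworthy: for rarely seen taxa the zeros dominate and bimodality
distorts rank statistics. The stratified procedure codes each taxon by its
detection rate (fraction of samples where it is observed):

* detection >= ``high``: treated as quantitative, but zeros are recoded to
  missing — an undetected core taxon is read as escaping detection, not as
  true absence;
* ``low`` <= detection < ``high``: dichotomized to presence/absence;
* detection < ``low``: excluded, too sparse to test.

Correlations are rank-based (Spearman) by default; a product-moment
(Pearson) policy for the high-detection stratum is available, matching the
convention of correlating biochemical indicators on the original scale.
q-values control FDR by Benjamini-Hochberg within one taxonomic level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, check_aligned
from .eqtl import bh_fdr

QUANT = "quantitative-with-NA"
BINARY = "binary"
EXCLUDED = "excluded"

MIN_COMPLETE_PAIRS = 10


def alpha_diversity(A: AbundanceTable) -> pd.DataFrame:
    """Shannon (nats) and Gini-Simpson indices per sample.

    Rows are renormalized to sum 1 over the retained taxa first, so the
    indices are well defined after QC filtering. All-zero rows yield NaN.
    """
    x = A.rel_abundance
    rowsum = x.sum(axis=1)
    shannon = np.full(A.n_samples, np.nan)
    simpson = np.full(A.n_samples, np.nan)
    ok = rowsum > 0
    p = x[ok] / rowsum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon[ok] = -plogp.sum(axis=1)
    simpson[ok] = 1.0 - (p**2).sum(axis=1)
    return pd.DataFrame(
        {"sample_id": A.sample_ids, "shannon": shannon, "simpson": simpson}
    )


def stratify_taxa(A: AbundanceTable, high: float = 0.6, low: float = 0.3) -> pd.Series:
    """Assign each taxon a coding stratum by its detection rate."""
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    det = A.detection_rates()
    coding = np.where(det >= high, QUANT, np.where(det >= low, BINARY, EXCLUDED))
    return pd.Series(coding, index=A.taxon_meta["taxon_id"].to_numpy(), name="coding")


def taxon_phenotype_association(
    A: AbundanceTable,
    phenotype: np.ndarray | pd.Series,
    coding: pd.Series | None = None,
    method_policy: str = "spearman",
    high: float = 0.6,
    low: float = 0.3,
) -> pd.DataFrame:
    """Correlate each coded taxon abundance with the phenotype.

    method_policy:
      "spearman"     — rank-based correlation in every stratum (default);
      "pearson-high" — product-moment for the quantitative stratum,
                       rank-based for the binary stratum.

    Returns one row per taxon: taxon_id, level, detection_rate, coding,
    method, estimate, p_value, q_value, flag. Excluded and degenerate taxa
    carry NaN estimates; q-values are BH over the tested taxa of each
    taxonomic level.
    """
    if method_policy not in ("spearman", "pearson-high"):
        raise ValueError("method_policy must be 'spearman' or 'pearson-high'")
    y = np.asarray(phenotype, dtype=float).ravel()
    if y.size != A.n_samples:
        raise ValueError("phenotype length does not match sample count")
    if np.nanstd(y) == 0:
        raise ValueError("phenotype is constant")
    if coding is None:
        coding = stratify_taxa(A, high=high, low=low)
    check_aligned(
        list(coding.index), list(A.taxon_meta["taxon_id"]), "coding vs abundance taxa"
    )

    det = A.detection_rates()
    rows = []
    for j, taxon in enumerate(A.taxon_meta["taxon_id"]):
        code = coding.iloc[j]
        level = A.taxon_meta["level"].iloc[j]
        base = dict(
            taxon_id=taxon, level=level, detection_rate=det[j], coding=code
        )
        if code == EXCLUDED:
            rows.append({**base, "method": None, "estimate": np.nan,
                         "p_value": np.nan, "flag": "excluded"})
            continue
        if code == QUANT:
            x = A.rel_abundance[:, j].astype(float).copy()
            x[x == 0] = np.nan  # zero in a core taxon = escaped detection
            method = "product-moment" if method_policy == "pearson-high" else "rank-based"
        else:
            x = (A.rel_abundance[:, j] > 0).astype(float)
            method = "rank-based"
        mask = ~np.isnan(x) & ~np.isnan(y)
        if mask.sum() < MIN_COMPLETE_PAIRS:
            rows.append({**base, "method": method, "estimate": np.nan,
                         "p_value": np.nan, "flag": "too-few-pairs"})
            continue
        xv, yv = x[mask], y[mask]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append({**base, "method": method, "estimate": np.nan,
                         "p_value": np.nan, "flag": "degenerate-coding"})
            continue
        if method == "product-moment":
            est, p = stats.pearsonr(xv, yv)
        else:
            est, p = stats.spearmanr(xv, yv)
        rows.append({**base, "method": method, "estimate": float(est),
                     "p_value": float(p), "flag": ""})

    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for level in out["level"].unique():
        sel = (out["level"] == level) & out["p_value"].notna()
        if sel.any():
            out.loc[sel, "q_value"] = bh_fdr(out.loc[sel, "p_value"].to_numpy())
    return out
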