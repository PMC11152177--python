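"""Core in-memory containers shared across the pipeline.

All numeric tables carry an ordered ``sample_ids`` list; alignment between
tables is always checked by ID, never assumed from row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype call in integer dosage arrays


class AlignmentError(ValueError):
    """Sample IDs of two tables do not match."""


class DegenerateInputError(ValueError):
    """Input has no usable information (all monomorphic / all constant)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosage matrix.

    dosages : int array (n, m) with entries in {0, 1, 2} or MISSING (-1).
    variant_meta : DataFrame with columns chrom, pos (1-based), ref, alt, id.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or missing (-1)")
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_meta)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_meta)} variants"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP over non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=0) / 2.0
        return np.asarray(p.filled(np.nan), dtype=float)

    def call_rate(self, axis: int) -> np.ndarray:
        """Fraction of non-missing calls per sample (axis=1) or SNP (axis=0)."""
        return (self.dosages != MISSING).mean(axis=axis)

    def imputed(self) -> np.ndarray:
        """Float dosages with missing entries mean-imputed to 2*p̄ per SNP."""
        x = self.dosages.astype(float)
        miss = self.dosages == MISSING
        if miss.any():
            fill = 2.0 * self.alt_freq()
            x[miss] = np.broadcast_to(fill, x.shape)[miss]
        return x


@dataclass
class RelationshipMatrix:
    """Symmetric n x n similarity kernel (GRM, sparse-GRM, or MRM)."""

    values: np.ndarray
    sample_ids: list[str]
    kind: str  # "GRM" | "sparse-GRM" | "MRM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be n x n")
        if not np.allclose(self.values, self.values.T, atol=0, rtol=0):
            raise ValueError("relationship matrix must be exactly symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances.

    rel_abundance : float array (n, k), nonnegative; rows sum to 1 over the
    taxa present at generation time (QC filtering may break closure, which is
    deliberate: filtered tables retain the original relative scale).
    taxon_meta : DataFrame with columns taxon_id, level, detection_rate.
    """

    rel_abundance: np.ndarray
    taxon_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if (self.rel_abundance < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.rel_abundance.shape != (len(self.sample_ids), len(self.taxon_meta)):
            raise ValueError("abundance shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.rel_abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.rel_abundance.shape[1]

    def detection_rates(self) -> np.ndarray:
        """Fraction of samples with nonzero abundance, per taxon."""
        return (self.rel_abundance > 0).mean(axis=0)


def check_aligned(ids_a: list[str], ids_b: list[str], what: str = "tables") -> None:
    if list(ids_a) != list(ids_b):
        raise AlignmentError(f"sample IDs of {what} do not match")
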