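import numpy as np
import pandas as pd
import pytest

from holovar import (
    AbundanceTable,
    GenotypeMatrix,
    RelationshipMatrix,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort with both genetic and microbial signal, shared
    read-only across tests."""
    cfg = SimConfig(
        n_individuals=300,
        n_snps=500,
        n_asvs=120,
        n_causal_snps=80,
        n_causal_taxa=30,
        h2_true=0.3,
        m2_true=0.2,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, chrom=None, pos=None):
    """Hand-built GenotypeMatrix for small fixtures."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "id": [f"v{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(
        dosages=dosages, variant_meta=meta, sample_ids=[f"s{i}" for i in range(n)]
    )


def make_abundance(rel, level="ASV"):
    rel = np.asarray(rel, dtype=float)
    n, k = rel.shape
    meta = pd.DataFrame(
        {
            "taxon_id": [f"t{j}" for j in range(k)],
            "level": [level] * k,
            "detection_rate": (rel > 0).mean(axis=0),
        }
    )
    return AbundanceTable(
        rel_abundance=rel, taxon_meta=meta, sample_ids=[f"s{i}" for i in range(n)]
    )
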