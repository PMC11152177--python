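"""Expression preprocessing, cis/trans windowing, SMR closed form, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holovar import (
    ExpressionMatrix,
    bh_fdr,
    compute_tpm,
    filter_normalize_expression,
    map_cis_eqtl,
    map_trans_eqtl,
    simulate_expression,
    simulate_genotypes,
    smr_batch,
    smr_test,
    tmm_factors,
)


def tmm_oracle(counts, ref, sample, logratio_trim=0.30, abs_trim=0.05):
    """Independent trimmed-mean-of-M computation, written directly from the
    definition: rank-trim M and A, precision-weighted mean of surviving M."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    both = (x[:, sample] > 0) & (x[:, ref] > 0)
    y, yr = x[both, sample], x[both, ref]
    n, nr = lib[sample], lib[ref]
    m = np.log2((y / n) / (yr / nr))
    a = 0.5 * np.log2((y / n) * (yr / nr))
    lm, hm = np.quantile(m, [logratio_trim, 1 - logratio_trim])
    la, ha = np.quantile(a, [abs_trim, 1 - abs_trim])
    keep = (m >= lm) & (m <= hm) & (a >= la) & (a <= ha)
    w = 1.0 / ((n - y) / (n * y) + (nr - yr) / (nr * yr))
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


@pytest.fixture(scope="module")
def expression_setup():
    g = simulate_genotypes(300, 60, seed=41)
    ann = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chrom": ["1", "1", "1", "1", "2", "2"],
            "tss": [1000, 10_000, 25_000, 40_000, 5_000, 30_000],
            "length": [1200, 900, 1500, 2000, 1100, 1300],
        }
    )
    plan = [("g0", "snp1", 1.2, "cis")]
    counts, lengths = simulate_expression(g, ann, plan, seed=41)
    E = ExpressionMatrix(counts=counts, lengths=lengths)
    return g, ann, filter_normalize_expression(E)


class TestExpressionNormalization:
    def test_tpm_columns_sum_to_a_million(self, expression_setup):
        _, _, E = expression_setup
        np.testing.assert_allclose(E.tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_low_tpm_gene_removed(self):
        counts = pd.DataFrame(
            {"s1": [1, 5000], "s2": [1, 6000]}, index=["low", "high"]
        )
        lengths = pd.Series([1000.0, 1000.0], index=["low", "high"])
        E = filter_normalize_expression(
            ExpressionMatrix(counts=counts, lengths=lengths),
            tpm_min=0.1, read_min=6, sample_fraction=0.2,
        )
        assert list(E.counts.index) == ["high"]

    def test_identical_columns_give_unit_tmm_factors(self):
        col = np.array([10, 200, 3000, 50, 400])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_tmm_matches_independent_oracle(self, rng):
        counts = pd.DataFrame(
            rng.poisson([200, 800, 50, 3000, 120, 640, 90, 1500, 2200, 330],
                        size=(6, 10)).T,
            columns=[f"s{i}" for i in range(6)],
        )
        counts.iloc[:, 2] *= 3  # composition shift
        f = tmm_factors(counts)
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        frac = counts.to_numpy() / lib
        uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75)
                       for j in range(6)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        raw = np.array([tmm_oracle(counts, ref, j) for j in range(6)])
        raw /= np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(f.to_numpy(), raw, atol=0.02)

    def test_zero_length_gene_rejected(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g"])
        with pytest.raises(ValueError):
            ExpressionMatrix(counts=counts, lengths=pd.Series([0.0], index=["g"]))


class TestCisTransWindows:
    def test_window_boundary_inclusive(self, expression_setup):
        g, ann, E = expression_setup
        # g0 TSS=1000; snp at pos 11000 is exactly TSS + window for window=10000
        res = map_cis_eqtl(E, g, ann, window=10_000, n_perm=0)
        g0 = res[res.gene_id == "g0"]
        assert (g0.distance.abs() <= 10_000).all()
        assert 10_000 in g0.distance.abs().to_numpy()

    def test_planted_effect_hits_minimum_empirical_p(self, expression_setup):
        g, ann, E = expression_setup
        res = map_cis_eqtl(E, g, ann, window=10_000, n_perm=200, seed=2)
        p_emp = res.loc[res.gene_id == "g0", "p_empirical"].iloc[0]
        assert p_emp == pytest.approx(1 / 201)

    def test_null_empirical_p_not_extreme(self, expression_setup):
        g, ann, E = expression_setup
        res = map_cis_eqtl(E, g, ann, window=10_000, n_perm=50, seed=3)
        null_genes = res[res.gene_id != "g0"].groupby("gene_id")["p_empirical"].first()
        assert (null_genes > 1 / 51).all()

    def test_gap_between_cis_window_and_trans_exclusion(self, expression_setup):
        """A variant between the cis window and the trans exclusion zone is
        tested in neither mode."""
        g, ann, E = expression_setup
        cis = map_cis_eqtl(E, g, ann, window=5_000, n_perm=0)
        trans = map_trans_eqtl(E, g, ann, exclusion=20_000, maf_min=0.0)
        # g2 TSS = 25000; snp10 at pos 10000 -> distance 15000: in the gap
        cis_pairs = set(zip(cis.gene_id, cis.variant_id))
        trans_pairs = set(zip(trans.gene_id, trans.variant_id))
        assert ("g2", "snp10") not in cis_pairs
        assert ("g2", "snp10") not in trans_pairs
        assert not cis_pairs & trans_pairs  # partitions disjoint

    def test_other_chromosome_always_trans_eligible(self, expression_setup):
        g, ann, E = expression_setup
        trans = map_trans_eqtl(E, g, ann, exclusion=20_000, maf_min=0.0)
        g4 = trans[trans.gene_id == "g4"]  # gene on chrom 2, snps on chrom 1
        assert len(g4) == g.n_variants

    def test_maf_floor_applied_to_trans(self, expression_setup):
        g, ann, E = expression_setup
        p = g.alt_freq()
        maf = np.minimum(p, 1 - p)
        trans = map_trans_eqtl(E, g, ann, exclusion=20_000, maf_min=0.3)
        tested = set(trans.variant_id)
        allowed = set(g.variant_meta["id"][maf > 0.3])
        assert tested <= allowed

    def test_planted_trans_effect_reaches_genome_wide(self):
        g = simulate_genotypes(500, 30, seed=44)
        # several null genes so library size varies and CPM carries signal
        ann = pd.DataFrame(
            {"gene_id": [f"gt{i}" for i in range(5)], "chrom": ["9"] * 5,
             "tss": [1000, 2000, 3000, 4000, 5000], "length": [1000] * 5}
        )
        counts, lengths = simulate_expression(
            g, ann, [("gt0", "snp5", 1.0, "trans")], seed=44, dispersion=0.05
        )
        E = filter_normalize_expression(ExpressionMatrix(counts=counts, lengths=lengths))
        res = map_trans_eqtl(E, g, ann, exclusion=5_000_000, maf_min=0.0)
        p = res.loc[(res.variant_id == "snp5") & (res.gene_id == "gt0"),
                    "p_nominal"].iloc[0]
        assert p < 3.32e-7


class TestSmr:
    def test_hand_computed_example(self):
        r = smr_test(0.5, 0.05, 0.2, 0.04)
        assert r.b_xy == pytest.approx(0.4)
        assert r.t_smr == pytest.approx(20.0)  # (100*25)/125
        assert r.p_smr == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_null_trait_association_gives_zero(self):
        r = smr_test(0.5, 0.05, 0.0, 0.04)
        assert r.b_xy == 0.0 and r.t_smr == 0.0 and r.p_smr == 1.0

    def test_statistic_symmetric_in_z_scores(self):
        a = smr_test(0.5, 0.1, 0.3, 0.06)
        b = smr_test(0.3, 0.06, 0.5, 0.1)
        assert a.t_smr == pytest.approx(b.t_smr)
        assert a.p_smr == pytest.approx(b.p_smr)

    def test_bounded_by_weaker_z_and_infinite_instrument_limit(self):
        z_g = 3.0
        prev = 0.0
        for z_e in (1.0, 5.0, 50.0, 5000.0):
            r = smr_test(z_e * 0.01, 0.01, z_g * 0.02, 0.02)
            assert r.t_smr <= min(z_e**2, z_g**2) + 1e-9
            assert r.t_smr >= prev
            prev = r.t_smr
        assert prev == pytest.approx(z_g**2, rel=1e-4)

    def test_zero_instrument_flagged(self):
        r = smr_test(0.0, 0.05, 0.2, 0.04)
        assert r.flagged and np.isnan(r.b_xy) and r.t_smr == 0.0

    def test_batch_joins_top_eqtl_to_gwas(self):
        eqtl = pd.DataFrame(
            {
                "gene_id": ["gA", "gA", "gB"],
                "variant_id": ["v1", "v2", "v3"],
                "beta": [0.5, 0.2, 0.4],
                "se": [0.05, 0.05, 0.08],
                "p_nominal": [1e-8, 1e-3, 1e-6],
            }
        )
        gwas = pd.DataFrame(
            {"id": ["v1", "v2", "v3"], "beta": [0.2, 0.1, 0.0], "se": [0.04, 0.04, 0.05]}
        )
        out = smr_batch(gwas, eqtl)
        assert list(out.gene_id) == ["gA", "gB"]
        assert out.loc[out.gene_id == "gA", "variant_id"].iloc[0] == "v1"
        assert out.loc[out.gene_id == "gA", "t_smr"].iloc[0] == pytest.approx(20.0)


class TestBhFdr:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_passthrough_and_all_ones(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_q_at_least_p_and_permutation_invariant(self, rng):
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))
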