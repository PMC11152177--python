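"""REML estimator against a brute-force grid-search oracle and recovery
simulations; permutation-null behavior."""

import numpy as np
import pytest

from holovar import (
    NonIdentifiableError,
    RelationshipMatrix,
    SimConfig,
    build_covariates,
    build_grm,
    build_mrm,
    estimate_h2,
    estimate_m2,
    permute_m2,
    reml_fit,
    simulate_cohort,
)
from holovar.relatedness import genetic_pcs
from holovar.varcomp import _profile_reml_loglik


def direct_reml_loglik(h, y, X, K):
    """Independent restricted log-likelihood: dense matrix algebra, no
    eigendecomposition shortcut, total variance profiled out."""
    n, p = X.shape
    V = h * K + (1 - h) * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    ypy = float(y @ P @ y)
    s2 = ypy / (n - p)
    sign, logdetV = np.linalg.slogdet(V)
    sign2, logdetX = np.linalg.slogdet(XtViX)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * s2) + logdetV + logdetX + (n - p)
    )


def random_instance(rng, n=30, p=2):
    z = rng.standard_normal((n, n + 5))
    K = z @ z.T / (n + 5)
    d = np.sqrt(np.diagonal(K))
    K = K / np.outer(d, d)  # unit diagonal, well away from identity
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    return y, X, K


class TestRemlAgainstGridOracle:
    def test_optimum_matches_grid_search(self, rng):
        """Fitted ratio within 0.002 of a 1001-point grid argmax of an
        independently coded restricted likelihood."""
        grid = np.linspace(0, 1, 1001)
        for _ in range(20):
            y, X, K = random_instance(rng)
            km = RelationshipMatrix(
                values=(K + K.T) / 2, sample_ids=[f"s{i}" for i in range(30)], kind="GRM"
            )
            fit = reml_fit(y, X, km)
            lls = [direct_reml_loglik(h, y, X, km.values) for h in grid[:-1]]
            h_grid = grid[int(np.argmax(lls))]
            assert fit.ratio == pytest.approx(h_grid, abs=0.002)

    def test_loglik_dominates_every_grid_point(self, rng):
        from holovar.varcomp import _project_out_covariates

        grid = np.linspace(0, 1, 1001)[:-1]
        for _ in range(5):
            y, X, K = random_instance(rng, n=40)
            km = RelationshipMatrix(
                values=(K + K.T) / 2, sample_ids=[f"s{i}" for i in range(40)], kind="GRM"
            )
            fit = reml_fit(y, X, km)
            d, w, _ = _project_out_covariates(y, X, km.values)
            best_grid = max(_profile_reml_loglik(h, d, w) for h in grid)
            assert fit.loglik >= best_grid - 1e-6


class TestParameterRecovery:
    def test_h2_recovered_at_half(self):
        est = []
        for r in range(10):
            cfg = SimConfig(n_individuals=400, n_snps=600, n_causal_snps=150,
                            h2_true=0.5, m2_true=0.0, seed=500 + r)
            b = simulate_cohort(cfg)
            est.append(estimate_h2(b.phenotypes, build_grm(b.genotypes)).ratio)
        assert np.mean(est) == pytest.approx(0.5, abs=0.07)

    def test_null_trait_estimates_near_zero(self):
        est = []
        for r in range(10):
            cfg = SimConfig(n_individuals=400, n_snps=600,
                            h2_true=0.0, m2_true=0.0, seed=600 + r)
            b = simulate_cohort(cfg)
            est.append(estimate_h2(b.phenotypes, build_grm(b.genotypes)).ratio)
        assert np.mean(est) < 0.05

    def test_batch_only_trait_absorbed_by_covariates(self, small_cohort):
        ph = small_cohort.phenotypes.copy()
        batch_codes = ph["batch"].astype("category").cat.codes.to_numpy()
        ph["trait"] = batch_codes * 2.0  # pure fixed effect, zero df for kernel
        grm = build_grm(small_cohort.genotypes)
        fit = estimate_h2(ph, grm)
        assert fit.ratio < 0.05

    def test_m2_invariant_to_abundance_rescaling(self, small_cohort):
        from holovar import AbundanceTable

        a = small_cohort.abundances
        scaled = AbundanceTable(
            rel_abundance=a.rel_abundance * 7.0,
            taxon_meta=a.taxon_meta,
            sample_ids=list(a.sample_ids),
        )
        f1 = estimate_m2(small_cohort.phenotypes, build_mrm(a))
        f2 = estimate_m2(small_cohort.phenotypes, build_mrm(scaled))
        assert f1.ratio == pytest.approx(f2.ratio, abs=1e-9)


class TestInvariances:
    def test_ratio_invariant_to_affine_trait_transform(self, rng):
        y, X, K = random_instance(rng, n=50)
        km = RelationshipMatrix(
            values=(K + K.T) / 2, sample_ids=[f"s{i}" for i in range(50)], kind="GRM"
        )
        f1 = reml_fit(y, X, km)
        f2 = reml_fit(3.5 * y - 2.0, X, km)
        assert f1.ratio == pytest.approx(f2.ratio, abs=1e-6)

    def test_kernel_rescaling_compensated_by_sigma2(self, rng):
        y, X, K = random_instance(rng, n=50)
        K = (K + K.T) / 2
        ids = [f"s{i}" for i in range(50)]
        f1 = reml_fit(y, X, RelationshipMatrix(values=K, sample_ids=ids, kind="GRM"))
        f2 = reml_fit(y, X, RelationshipMatrix(values=2 * K, sample_ids=ids, kind="GRM"))
        v1 = f1.sigma2_kernel * 1.0
        v2 = f2.sigma2_kernel * 2.0
        # kernel-scale covariance (sigma2 * K) is what the model sees
        assert v1 == pytest.approx(v2, rel=0.05)

    def test_identity_kernel_not_identifiable(self, rng):
        y = rng.standard_normal(30)
        X = np.ones((30, 1))
        km = RelationshipMatrix(
            values=np.eye(30), sample_ids=[f"s{i}" for i in range(30)], kind="GRM"
        )
        with pytest.raises(NonIdentifiableError):
            reml_fit(y, X, km)

    def test_rank_deficient_covariates_rejected(self, rng):
        y, X, K = random_instance(rng, n=30)
        X = np.column_stack([X, X[:, 0]])
        km = RelationshipMatrix(
            values=(K + K.T) / 2, sample_ids=[f"s{i}" for i in range(30)], kind="GRM"
        )
        with pytest.raises(ValueError, match="rank"):
            reml_fit(y, X, km)


class TestPermutationNull:
    def test_true_signal_detected(self):
        cfg = SimConfig(n_individuals=400, n_snps=200, n_asvs=150,
                        h2_true=0.0, m2_true=0.3, seed=700)
        b = simulate_cohort(cfg)
        mrm = build_mrm(b.abundances)
        X = build_covariates(b.phenotypes)
        res = permute_m2(b.phenotypes["trait"].to_numpy(), X, mrm, n_perm=99, seed=1)
        assert res.p_value <= 0.05

    def test_p_value_never_zero_and_addone_rule(self):
        cfg = SimConfig(n_individuals=200, n_snps=100, n_asvs=80,
                        h2_true=0.0, m2_true=0.6, seed=701)
        b = simulate_cohort(cfg)
        mrm = build_mrm(b.abundances)
        X = build_covariates(b.phenotypes)
        res = permute_m2(b.phenotypes["trait"].to_numpy(), X, mrm, n_perm=19, seed=2)
        assert res.p_value > 0
        expected = (1 + (res.permuted_ratios >= res.observed_ratio).sum()) / 20
        assert res.p_value == pytest.approx(expected)
        assert len(res.permuted_ratios) == 19

    def test_deterministic_given_seed(self, small_cohort):
        mrm = build_mrm(small_cohort.abundances)
        X = build_covariates(small_cohort.phenotypes)
        y = small_cohort.phenotypes["trait"].to_numpy()
        r1 = permute_m2(y, X, mrm, n_perm=10, seed=5)
        r2 = permute_m2(y, X, mrm, n_perm=10, seed=5)
        np.testing.assert_array_equal(r1.permuted_ratios, r2.permuted_ratios)

    def test_null_permuted_ratios_stay_small(self):
        """Independent phenotype: permuted estimates average in the same
        low range as the observed null."""
        cfg = SimConfig(n_individuals=300, n_snps=100, n_asvs=150,
                        h2_true=0.0, m2_true=0.0, seed=702)
        b = simulate_cohort(cfg)
        mrm = build_mrm(b.abundances)
        X = build_covariates(b.phenotypes)
        res = permute_m2(b.phenotypes["trait"].to_numpy(), X, mrm, n_perm=30, seed=3)
        assert res.permuted_ratios.mean() < 0.1
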