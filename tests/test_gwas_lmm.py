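"""GRM construction, covariates, REML and the mixed-model scan."""

import numpy as np
import pytest
from scipy import stats

from pleiosweep.gwas_lmm import (
    GRM,
    VarianceComponents,
    build_covariates,
    compute_grm,
    compute_heterozygosity,
    compute_pcs,
    mlma_scan,
    reml_fit,
)

from conftest import make_geno, random_geno


class TestGrm:
    def test_all_heterozygous_gives_zero_matrix(self):
        geno = make_geno(np.ones((4, 1)))
        g = compute_grm(geno).matrix
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_exact_symmetry(self, rng):
        geno = random_geno(rng, 20, 50)
        g = compute_grm(geno).matrix
        assert np.array_equal(g, g.T)

    def test_direct_formula_oracle(self):
        dosage = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], float)
        geno = make_geno(dosage)
        g = compute_grm(geno).matrix
        p = dosage.mean(axis=0) / 2
        n, m = dosage.shape
        expected = np.zeros((n, n))
        for j in range(n):
            for k in range(n):
                expected[j, k] = sum(
                    (dosage[j, i] - 2 * p[i]) * (dosage[k, i] - 2 * p[i])
                    / (2 * p[i] * (1 - p[i]))
                    for i in range(m)
                ) / m
        np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_monomorphic_skipped_and_all_mono_errors(self):
        geno = make_geno(np.column_stack([np.ones(4), np.full(4, 2.0)]))
        # one polymorphic-ish column (all het) is fine; all-monomorphic errors
        compute_grm(geno)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_geno(np.full((4, 2), 2.0)))


class TestHeterozygosity:
    @pytest.mark.parametrize("dosage,expected", [
        (np.ones((1, 10)), 1.0),
        (np.full((1, 10), 2.0), 0.0),
        (np.array([[1, 1, 1, 0, 0, 2, 2, 0, 2, 0]], float), 0.3),
    ])
    def test_proportions(self, dosage, expected):
        assert compute_heterozygosity(make_geno(dosage))[0] == pytest.approx(expected)


class TestPcs:
    def test_two_clusters_separated_on_pc1(self, rng):
        a = rng.binomial(2, 0.1, size=(15, 60)).astype(float)
        b = rng.binomial(2, 0.9, size=(15, 60)).astype(float)
        geno = make_geno(np.vstack([a, b]))
        pcs = compute_pcs(geno, k=4)
        pa, pb = pcs[:15, 0], pcs[15:, 0]
        assert max(pa.max(), pb.max()) == max(pa.max(), pb.max())
        assert (pa.max() < pb.min()) or (pb.max() < pa.min())

    def test_duplicate_samples_identical_scores(self, rng):
        x = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(10, 30)).astype(float)
        geno = make_geno(np.vstack([x, x[:1]]))
        pcs = compute_pcs(geno, k=3)
        np.testing.assert_allclose(pcs[0], pcs[10], atol=1e-8)

    def test_variance_explained_non_increasing(self, rng):
        geno = random_geno(rng, 30, 80)
        pcs = compute_pcs(geno, k=4)
        var = pcs.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            compute_pcs(random_geno(rng, 4, 10), k=4)


@pytest.fixture(scope="module")
def grm500():
    # a modest marker count keeps the GRM off-diagonal spread wide enough for
    # well-conditioned variance-component estimation at n = 500
    rng = np.random.default_rng(77)
    geno = random_geno(rng, 500, 80)
    return compute_grm(geno)


class TestReml:

    def test_pure_noise_gives_near_zero_genetic_variance(self, grm500):
        rng = np.random.default_rng(1)
        n = 500
        x = np.ones((n, 1))
        hits = 0
        reps = 50
        for _ in range(reps):
            vc = reml_fit(rng.normal(size=n), x, grm500)
            hits += vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2) < 0.05
        assert hits >= 0.9 * reps

    def test_h2_recovery(self, grm500):
        rng = np.random.default_rng(2)
        n = 500
        d, u = np.linalg.eigh(grm500.matrix)
        d = np.clip(d, 0, None)
        x = np.ones((n, 1))
        hits = 0
        reps = 50
        for _ in range(reps):
            g = u @ (np.sqrt(d) * rng.normal(size=n))
            g = g / g.std() * np.sqrt(0.5)
            y = g + rng.normal(scale=np.sqrt(0.5), size=n)
            vc = reml_fit(y, x, grm500)
            hits += abs(vc.heritability - 0.5) <= 0.15
        assert hits >= 0.8 * reps

    def test_scale_equivariance(self, grm500):
        rng = np.random.default_rng(3)
        y = rng.normal(size=500) + grm500.matrix @ rng.normal(size=500) * 0.05
        x = np.ones((500, 1))
        vc1 = reml_fit(y, x, grm500)
        vc2 = reml_fit(2 * y, x, grm500)
        assert vc2.sigma_g2 == pytest.approx(4 * vc1.sigma_g2, rel=1e-3, abs=1e-8)
        assert vc2.sigma_e2 == pytest.approx(4 * vc1.sigma_e2, rel=1e-3)

    def test_too_few_observations_errors(self, grm500):
        y = np.full(500, np.nan)
        y[:3] = 1.0
        with pytest.raises(ValueError):
            reml_fit(y, np.ones((500, 4)), grm500)


class TestMlmaScan:
    def test_ols_oracle_when_no_genetic_variance(self, rng):
        """With sigma_g^2 fixed at 0 the scan reduces to ordinary least
        squares of y on (covariates, SNP): betas and SEs must match an
        explicit normal-equations oracle to 1e-8 relative."""
        n, m = 200, 40
        geno = random_geno(rng, n, m)
        covar = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        vc = VarianceComponents(0.0, 1.0, 0.0)
        grm = compute_grm(geno)
        scan = mlma_scan(y, covar, grm, geno, vc=vc)
        for j in range(m):
            a = np.column_stack([covar, geno.dosage[:, j]])
            ata = a.T @ a
            coef = np.linalg.solve(ata, a.T @ y)
            resid = y - a @ coef
            sigma2 = resid @ resid / (n - a.shape[1])
            se = np.sqrt(sigma2 * np.linalg.inv(ata)[-1, -1])
            assert scan["beta"].iloc[j] == pytest.approx(coef[-1], rel=1e-8, abs=1e-10)
            assert scan["se"].iloc[j] == pytest.approx(se, rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, m = 400, 2000
        geno = random_geno(rng, n, m)
        grm = compute_grm(geno)
        y = rng.normal(size=n)
        scan = mlma_scan(y, np.ones((n, 1)), grm, geno)
        frac = float((scan["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_null_p_uniform(self):
        rng = np.random.default_rng(12)
        n, m = 300, 2000
        geno = random_geno(rng, n, m)
        grm = GRM(np.zeros((n, n)), geno.samples)  # sigma_g2 = 0 regime
        vc = VarianceComponents(0.0, 1.0, 0.0)
        y = rng.normal(size=n)
        scan = mlma_scan(y, np.ones((n, 1)), grm, geno, vc=vc)
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_effect_recovery_within_two_se(self, rng):
        n = 400
        geno = random_geno(rng, n, 30)
        w = geno.dosage[:, 7]
        y = 0.5 * w + rng.normal(size=n)
        scan = mlma_scan(y, np.ones((n, 1)), compute_grm(geno), geno)
        row = scan.iloc[7]
        assert abs(row["beta"] - 0.5) < 2 * row["se"]

    def test_signed_t_equals_beta_over_se(self, rng):
        n = 150
        geno = random_geno(rng, n, 25)
        scan = mlma_scan(rng.normal(size=n), np.ones((n, 1)), compute_grm(geno), geno)
        ok = ~scan["collinear"]
        np.testing.assert_array_equal(
            scan.loc[ok, "t"], scan.loc[ok, "beta"] / scan.loc[ok, "se"]
        )

    def test_collinear_snp_flagged(self, rng):
        n = 100
        geno = random_geno(rng, n, 5)
        covar = np.column_stack([np.ones(n), geno.dosage[:, 2]])
        scan = mlma_scan(rng.normal(size=n), covar, compute_grm(geno), geno)
        assert bool(scan["collinear"].iloc[2])
        assert scan["se"].iloc[2] == np.inf
        assert scan["p"].iloc[2] == 1.0

    def test_sample_order_invariance(self, rng):
        n = 120
        geno = random_geno(rng, n, 30)
        y = rng.normal(size=n)
        covar = np.column_stack([np.ones(n), rng.normal(size=n)])
        grm = compute_grm(geno)
        scan1 = mlma_scan(y, covar, grm, geno)
        perm = rng.permutation(n)
        from pleiosweep.genio import GenotypeMatrix

        geno_p = GenotypeMatrix(
            geno.variants, [geno.samples[i] for i in perm], geno.dosage[perm]
        )
        grm_p = GRM(grm.matrix[np.ix_(perm, perm)], geno_p.samples)
        scan2 = mlma_scan(y[perm], covar[perm], grm_p, geno_p)
        # agreement is limited by the REML optimiser tolerance, not by the
        # sample ordering itself
        np.testing.assert_allclose(scan1["beta"], scan2["beta"], rtol=1e-5)
        np.testing.assert_allclose(scan1["p"], scan2["p"], rtol=1e-4)


class TestCovariates:
    def test_one_hot_drops_first_level_and_keeps_singletons(self):
        x = build_covariates(groups=["a", "b", "b", "c"])
        assert x.shape == (4, 3)  # intercept + 2 group indicators
        np.testing.assert_array_equal(x[:, 0], 1.0)
        assert x[:, 1].tolist() == [0, 1, 1, 0]  # level b
        assert x[:, 2].tolist() == [0, 0, 0, 1]  # singleton level c retained
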