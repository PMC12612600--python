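import numpy as np
import pandas as pd
import pytest
from helpers import (
    dense_kron,
    iid_restricted_loglik,
    naive_blups,
    naive_restricted_loglik,
)

from orchardqg.genomics import GrMatrix
from orchardqg.mixed_models import (
    FitControls,
    GeneticCovariance,
    ModelError,
    ResidualCovariance,
    ar1_correlation,
    assemble_genetic_covariance,
    assemble_residual_covariance,
    build_bivariate_data,
    build_model_data,
    clonal_rankings,
    fit_reml,
    lrt,
    restricted_loglik,
)
from orchardqg.synthetic import SimulationConfig, simulate_phenotypes, simulate_study


class TestAr1Correlation:
    def test_zero_rho_identity(self):
        np.testing.assert_array_equal(ar1_correlation(0.0, [1, 5, 9]), np.eye(3))

    def test_definition(self):
        np.testing.assert_allclose(
            ar1_correlation(0.5, [1, 2]), [[1, 0.5], [0.5, 1]]
        )

    @pytest.mark.parametrize("rho", [-0.7, 0.3, 0.9])
    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_determinant_closed_form(self, rho, n):
        m = ar1_correlation(rho, np.arange(1, n + 1))
        assert np.linalg.det(m) == pytest.approx((1 - rho**2) ** (n - 1), rel=1e-9)

    def test_invalid_rho(self):
        with pytest.raises(ModelError):
            ar1_correlation(1.0, [1, 2])


class TestAssembleGeneticCovariance:
    def test_identity_blocks(self):
        g = GeneticCovariance(variances=(1.0, 1.0), covariance=0.0)
        k = GrMatrix(clone_ids=["a", "b", "c"], values=np.eye(3), n_snps_used=1)
        np.testing.assert_array_equal(assemble_genetic_covariance(g, k), np.eye(6))

    def test_kron_with_identity(self):
        g = GeneticCovariance(variances=(4.0, 1.0), covariance=2.0)
        k = GrMatrix(clone_ids=["a", "b"], values=np.eye(2), n_snps_used=1)
        out = assemble_genetic_covariance(g, k)
        np.testing.assert_array_equal(out[:2, :2], 4 * np.eye(2))
        np.testing.assert_array_equal(out[:2, 2:], 2 * np.eye(2))
        np.testing.assert_array_equal(out[2:, 2:], np.eye(2))

    def test_matches_bruteforce_kron(self):
        rng = np.random.default_rng(0)
        a = rng.random((3, 3))
        kv = a @ a.T + np.eye(3)
        k = GrMatrix(clone_ids=["a", "b", "c"], values=kv, n_snps_used=1)
        g = GeneticCovariance(variances=(2.0, 0.5), covariance=0.7)
        np.testing.assert_allclose(
            assemble_genetic_covariance(g, k), dense_kron(g.matrix(), kv)
        )


class TestAssembleResidualCovariance:
    def test_nugget_only(self):
        design = pd.DataFrame(
            {"site": ["S1"] * 3, "row": [1, 2, 3], "col": [1, 1, 1]}
        )
        r = ResidualCovariance(
            spatial_variance=(0.0,), rho_col=(0.3,), rho_row=(0.3,), nugget=(2.0,)
        )
        np.testing.assert_allclose(
            assemble_residual_covariance(r, design), 2.0 * np.eye(3)
        )

    def test_formula_evaluation(self):
        design = pd.DataFrame({"site": ["S1", "S1"], "row": [4, 4], "col": [2, 3]})
        r = ResidualCovariance(
            spatial_variance=(1.0,), rho_col=(0.4,), rho_row=(0.9,), nugget=(0.5,)
        )
        out = assemble_residual_covariance(r, design)
        np.testing.assert_allclose(out, [[1.5, 0.4], [0.4, 1.5]])

    def test_cross_site_zero(self):
        design = pd.DataFrame({"site": ["S1", "S2"], "row": [1, 1], "col": [1, 1]})
        r = ResidualCovariance(
            spatial_variance=(1.0, 1.0), rho_col=(0.5, 0.5),
            rho_row=(0.5, 0.5), nugget=(0.1, 0.1),
        )
        out = assemble_residual_covariance(r, design)
        assert out[0, 1] == 0.0

    def test_duplicate_cell_rejected(self):
        design = pd.DataFrame({"site": ["S1", "S1"], "row": [1, 1], "col": [2, 2]})
        r = ResidualCovariance(
            spatial_variance=(1.0,), rho_col=(0.5,), rho_row=(0.5,), nugget=(0.1,)
        )
        with pytest.raises(ModelError):
            assemble_residual_covariance(r, design)


def _random_instance(rng, n_sites=1, n_clones=4, n_per_site=10):
    """A small random study plus random covariance parameters."""
    cfg = SimulationConfig(
        n_clones=n_clones, ramets_per_site=(n_per_site,) * n_sites
        if n_sites > 1 else n_per_site,
        n_sites=n_sites, grid_rows=5, grid_cols=4, n_snps=50,
        true_genetic_variance=0.5, true_spatial_variance=0.2,
        true_nugget=0.5, seed=int(rng.integers(2**31 - 1)),
    )
    from orchardqg.synthetic import simulate_orchard_design

    design = simulate_orchard_design(cfg, int(rng.integers(2**31 - 1)))
    a = rng.random((n_clones, n_clones))
    kv = a @ a.T / n_clones + np.eye(n_clones)
    grm = GrMatrix(
        clone_ids=[f"C{i + 1:03d}" for i in range(n_clones)], values=kv, n_snps_used=50
    )
    study = simulate_phenotypes(design, grm, cfg, int(rng.integers(2**31 - 1)))
    data = build_model_data(study.phenotypes, study.phenotypes["value"], grm)
    vas = tuple(rng.uniform(0.1, 2.0, n_sites))
    ra = rng.uniform(-0.8, 0.8)
    g = GeneticCovariance(
        variances=vas,
        covariance=ra * np.sqrt(np.prod(vas)) if n_sites == 2 else 0.0,
    )
    r = ResidualCovariance(
        spatial_variance=tuple(rng.uniform(0.05, 1.0, n_sites)),
        rho_col=tuple(rng.uniform(-0.6, 0.8, n_sites)),
        rho_row=tuple(rng.uniform(-0.6, 0.8, n_sites)),
        nugget=tuple(rng.uniform(0.1, 1.0, n_sites)),
    )
    return data, g, r


class TestRestrictedLoglik:
    def test_matches_naive_oracle_randomized(self):
        """Exact agreement (1e-8) with a dense from-definition REML criterion
        on randomized small instances, one and two sites."""
        rng = np.random.default_rng(123)
        for i in range(25):
            n_sites = 1 if i % 2 == 0 else 2
            data, g, r = _random_instance(rng, n_sites=n_sites)
            ours = restricted_loglik(data, g, r)
            G = assemble_genetic_covariance(g, data.K)
            R = assemble_residual_covariance(r, data.design)
            ref = naive_restricted_loglik(data.y, data.X, data.Z, G, R)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_zero_genetic_iid_closed_form(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        design = pd.DataFrame(
            {
                "ramet_id": [f"r{i}" for i in range(30)],
                "site": "S1", "row": np.arange(30) // 5 + 1,
                "col": np.arange(30) % 5 + 1,
                "clone": [f"C{i % 3 + 1:03d}" for i in range(30)],
            }
        )
        grm = GrMatrix(
            clone_ids=["C001", "C002", "C003"], values=np.eye(3), n_snps_used=1
        )
        data = build_model_data(design, y, grm, use_population=False)
        _, s2 = iid_restricted_loglik(y)
        g = GeneticCovariance(variances=(0.0,))
        r = ResidualCovariance(
            spatial_variance=(0.0,), rho_col=(0.0,), rho_row=(0.0,), nugget=(s2,)
        )
        ll_ref, _ = iid_restricted_loglik(y)
        assert restricted_loglik(data, g, r) == pytest.approx(ll_ref, abs=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        data, g, r = _random_instance(rng)
        base = restricted_loglik(data, g, r)
        import dataclasses

        shifted = dataclasses.replace(data, y=data.y + data.X @ rng.normal(size=data.X.shape[1]))
        assert restricted_loglik(shifted, g, r) == pytest.approx(base, abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        data, g, r = _random_instance(rng)
        base = restricted_loglik(data, g, r)
        perm = rng.permutation(data.y.size)
        import dataclasses

        permuted = dataclasses.replace(
            data,
            y=data.y[perm], X=data.X[perm], Z=data.Z[perm],
            design=data.design.iloc[perm].reset_index(drop=True),
            group_of_obs=data.group_of_obs[perm],
            clone_of_obs=data.clone_of_obs[perm],
        )
        assert restricted_loglik(permuted, g, r) == pytest.approx(base, abs=1e-8)


class TestFitReml:
    def test_toy_matches_grid_polish_oracle(self, identity_grm):
        """20-ramet nugget-only fit vs an exhaustive grid + local polish over
        the naive dense restricted likelihood."""
        rng = np.random.default_rng(21)
        n, q = 20, 5
        clones = [f"C{i + 1:03d}" for i in range(q)]
        design = pd.DataFrame(
            {
                "ramet_id": [f"r{i}" for i in range(n)],
                "site": "S1", "row": np.arange(n) // 4 + 1, "col": np.arange(n) % 4 + 1,
                "clone": [clones[i % q] for i in range(n)],
            }
        )
        u = {c: rng.normal(scale=1.0) for c in clones}
        y = np.array([5 + u[c] for c in design["clone"]]) + rng.normal(
            scale=np.sqrt(0.5), size=n
        )
        grm = identity_grm(q)
        data = build_model_data(design, y, grm, use_population=False)
        fit = fit_reml(
            data, "multi_site_univariate", FitControls(spatial=False, compute_ai=False)
        )

        Zc = data.Z

        def nll(theta):
            va, ve = np.exp(theta)
            return -naive_restricted_loglik(
                data.y, data.X, Zc, va * np.eye(q), ve * np.eye(n)
            )

        grid = [
            (lv_a, lv_e)
            for lv_a in np.linspace(-4, 2, 25)
            for lv_e in np.linspace(-4, 2, 25)
        ]
        best = min(grid, key=nll)
        from scipy.optimize import minimize

        polish = minimize(nll, best, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12})
        va_ref, ve_ref = np.exp(polish.x)
        assert fit.genetic.variances[0] == pytest.approx(va_ref, abs=1e-3)
        assert fit.residual.nugget[0] == pytest.approx(ve_ref, abs=1e-3)
        assert fit.loglik == pytest.approx(-polish.fun, abs=1e-6)

    def test_spatial_structure_collapse(self, small_study):
        """With rho fixed at ~0 the spatial+nugget fit reproduces the
        nugget-only likelihood (model nesting)."""
        study = small_study
        data = build_model_data(study.phenotypes, study.phenotypes["value"], study.grm)
        nug = fit_reml(
            data, "multi_site_univariate", FitControls(spatial=False, compute_ai=False)
        )
        spat = fit_reml(
            data, "multi_site_univariate", FitControls(spatial=True, compute_ai=False)
        )
        # the spatial model nests the nugget-only model
        assert spat.loglik >= nug.loglik - 1e-5

    def test_null_genetic_variance_near_boundary(self, identity_grm):
        """Data with no genetic signal: sigma_a^2 lands at/near 0 and the
        boundary-mixture LRT is non-significant in most replicates."""
        rng = np.random.default_rng(3)
        n, q = 120, 20
        clones = [f"C{i + 1:03d}" for i in range(q)]
        rejections = 0
        reps = 20
        grm = identity_grm(q)
        design = pd.DataFrame(
            {
                "ramet_id": [f"r{i}" for i in range(n)],
                "site": "S1", "row": np.arange(n) // 11 + 1, "col": np.arange(n) % 11 + 1,
                "clone": [clones[i % q] for i in range(n)],
            }
        )
        for _ in range(reps):
            y = 5 + rng.normal(size=n)
            data = build_model_data(design, y, grm, use_population=False)
            full = fit_reml(
                data, "multi_site_univariate", FitControls(spatial=False, compute_ai=False)
            )
            red = fit_reml(
                data, "multi_site_univariate",
                FitControls(spatial=False, genetic=False, compute_ai=False),
            )
            _, p = lrt(full, red, "variance_on_boundary")
            rejections += p < 0.05
        assert rejections <= 0.10 * reps + 2

    def test_bivariate_nesting(self, tiny_grm, toy_design):
        """Bivariate restricted likelihood with both covariances at zero
        equals the sum of the two univariate (nugget-only) likelihoods."""
        rng = np.random.default_rng(9)
        design = toy_design.table.copy()
        design["clone"] = [f"C{i % 5 + 1:03d}" for i in range(len(design))]
        y1 = rng.normal(5, 1, len(design))
        y2 = rng.normal(7, 2, len(design))
        grm = tiny_grm
        biv = build_bivariate_data(design, y1, y2, grm, use_population=False)
        va1, va2, ve1, ve2 = 0.4, 0.9, 1.1, 2.3
        g_b = GeneticCovariance(variances=(va1, va2), covariance=0.0, structure="bivariate")
        r_b = ResidualCovariance(trait_variances=(ve1, ve2), trait_covariance=0.0)
        ll_biv = restricted_loglik(biv, g_b, r_b)
        ll_sum = 0.0
        for y, va, ve in ((y1, va1, ve1), (y2, va2, ve2)):
            d = build_model_data(design, y, grm, use_population=False)
            ll_sum += restricted_loglik(
                d,
                GeneticCovariance(variances=(va,)),
                ResidualCovariance(
                    spatial_variance=(0.0,), rho_col=(0.0,), rho_row=(0.0,), nugget=(ve,)
                ),
            )
        assert ll_biv == pytest.approx(ll_sum, abs=1e-6)

    def test_bivariate_matches_naive_oracle(self, tiny_grm, toy_design):
        rng = np.random.default_rng(31)
        design = toy_design.table.copy()
        design["clone"] = [f"C{i % 5 + 1:03d}" for i in range(len(design))]
        y1 = rng.normal(5, 1, len(design))
        y2 = rng.normal(7, 2, len(design))
        y2[3] = np.nan  # one unpaired unit
        data = build_bivariate_data(design, y1, y2, tiny_grm, use_population=False)
        g = GeneticCovariance(variances=(0.5, 0.8), covariance=0.3, structure="bivariate")
        r = ResidualCovariance(trait_variances=(1.0, 1.5), trait_covariance=0.6)
        ours = restricted_loglik(data, g, r)
        G = assemble_genetic_covariance(g, tiny_grm)
        n = data.y.size
        R = np.zeros((n, n))
        for i in range(n):
            R[i, i] = r.trait_variances[data.group_of_obs[i]]
        for i in range(n):
            for j in range(i + 1, n):
                if (
                    data.pair_index[i] == data.pair_index[j]
                    and data.group_of_obs[i] != data.group_of_obs[j]
                ):
                    R[i, j] = R[j, i] = r.trait_covariance
        ref = naive_restricted_loglik(data.y, data.X, data.Z, G, R)
        assert ours == pytest.approx(ref, abs=1e-8)


class TestLrt:
    def test_equal_likelihoods(self):
        stat, p = lrt(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_mixture_quantile(self):
        _, p = lrt(-98.645, -100.0, "variance_on_boundary")  # stat = 2.71
        assert p == pytest.approx(0.05, abs=0.001)

    def test_chi2_quantile(self):
        _, p = lrt(-98.08, -100.0, "covariance_zero")  # stat = 3.84
        assert p == pytest.approx(0.05, abs=0.001)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ModelError):
            lrt(-101.0, -100.0)


class TestClonalRankings:
    def test_blups_match_direct_formula(self, identity_grm):
        rng = np.random.default_rng(13)
        n, q = 18, 3
        clones = [f"C{i + 1:03d}" for i in range(q)]
        design = pd.DataFrame(
            {
                "ramet_id": [f"r{i}" for i in range(n)],
                "site": "S1", "row": np.arange(n) // 5 + 1, "col": np.arange(n) % 5 + 1,
                "clone": [clones[i % q] for i in range(n)],
            }
        )
        u = np.array([1.0, -0.5, 0.2])
        y = 5 + u[np.arange(n) % q] + rng.normal(scale=0.4, size=n)
        grm = identity_grm(q)
        data = build_model_data(design, y, grm, use_population=False)
        fit = fit_reml(
            data, "multi_site_univariate", FitControls(spatial=False, compute_ai=False)
        )
        G = assemble_genetic_covariance(fit.genetic, grm)
        R = fit.residual.nugget[0] * np.eye(n)
        ref = naive_blups(data.y, data.X, data.Z, G, R)
        np.testing.assert_allclose(fit.blups["blup"].to_numpy(), ref, atol=1e-5)
        ranked = clonal_rankings(fit)
        assert ranked.attrs["informative"]
        assert list(ranked["clone"][:1]) == ["C001"]

    def test_rank_stability_under_perfect_correlation(self, two_site_study):
        cfg = SimulationConfig(
            n_clones=15, ramets_per_site=(90, 90), n_sites=2,
            grid_rows=10, grid_cols=10, n_snps=600,
            true_genetic_variance=0.6, cross_site_genetic_correlation=1.0,
            true_spatial_variance=0.0, true_nugget=0.2, seed=17,
        )
        study = simulate_study(cfg)
        data = build_model_data(study.phenotypes, study.phenotypes["value"], study.grm)
        fit = fit_reml(
            data, "multi_site_univariate", FitControls(spatial=False, compute_ai=False)
        )
        ranked = clonal_rankings(fit)
        rho = list(ranked.attrs["rank_stability"].values())[0]
        assert rho > 0.9
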