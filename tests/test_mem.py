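"""Mixed-model machinery: designs, REML engine, plug-in MEM estimators."""

import numpy as np
import pytest

from lgpois import (CountDataset, InvalidInputError, RandomEffectDesign,
                    build_group_design, build_lowrank_gp_basis,
                    fit_comparator, fit_gaussian_mem_reml,
                    fit_irls_poisson, fit_mem_comparators, fit_mem_proposed,
                    fit_proposed)
from lgpois.mem import _penalized_wls
from conftest import make_dataset


class TestGroupDesign:
    def test_indicator_construction(self):
        b = build_group_design(["a", "a", "b"])
        np.testing.assert_array_equal(b.Z, [[1, 0], [1, 0], [0, 1]])

    def test_row_and_column_sums(self, rng):
        labels = rng.integers(0, 5, 60)
        b = build_group_design(labels)
        np.testing.assert_array_equal(b.Z.sum(axis=1), 1)
        np.testing.assert_array_equal(
            b.Z.sum(axis=0), np.bincount(labels, minlength=5))

    def test_single_level_rejected(self):
        with pytest.raises(InvalidInputError):
            build_group_design(["a", "a", "a"])


class TestLowrankGpBasis:
    def test_two_point_eigenproblem_by_hand(self):
        d, h = 2.0, 1.5
        rho = np.exp(-d / h)
        b = build_lowrank_gp_basis(np.array([[0, 0], [d, 0]]), rank=2,
                                   range_h=h)
        # implied covariance = sum of eigval * outer(eigvec); eigenvalues
        # of [[1, rho], [rho, 1]] are 1 +/- rho
        gram = b.Z.T @ b.Z
        np.testing.assert_allclose(sorted(np.diag(gram)), sorted([1 - rho, 1 + rho]),
                                   atol=1e-12)

    def test_full_rank_reproduces_kernel(self, rng):
        coords = rng.uniform(0, 1, (15, 2))
        h = 0.4
        b = build_lowrank_gp_basis(coords, rank=15, range_h=h)
        from scipy.spatial.distance import cdist
        kernel = np.exp(-cdist(coords, coords) / h)
        np.testing.assert_allclose(b.Z @ b.Z.T, kernel, atol=1e-10)

    def test_coincident_points_have_identical_rows(self):
        coords = np.array([[0.3, 0.3], [0.3, 0.3], [0.8, 0.1]])
        b = build_lowrank_gp_basis(coords, rank=2, range_h=1.0)
        np.testing.assert_allclose(b.Z[0], b.Z[1], atol=1e-12)

    def test_invalid_inputs(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(InvalidInputError):
            build_lowrank_gp_basis(coords, rank=5)
        with pytest.raises(InvalidInputError):
            build_lowrank_gp_basis(np.array([[0, np.nan], [1, 0]]))


class TestGaussianRemlEngine:
    def test_no_random_blocks_is_plain_wls(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 2.0] + rng.normal(0, 0.5, n)
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_gaussian_mem_reml(y, w, X, RandomEffectDesign())
        sw = np.sqrt(w)
        oracle, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-10)
        assert fit.edof == X.shape[1]

    def test_zero_residual_data_gives_zero_tau2(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, -1.0]  # exactly in the fixed-effect span
        design = RandomEffectDesign([build_group_design(rng.integers(0, 4, n))])
        fit = fit_gaussian_mem_reml(y, np.ones(n), X, design)
        assert np.all(fit.tau2 < 1e-6)

    def test_balanced_oneway_matches_closed_form_reml(self, rng):
        """Balanced one-way layout: REML equals the ANOVA estimators
        tau2 = (MSA - MSE)/n_per, phi = MSE."""
        n_groups, n_per = 8, 10
        g = np.repeat(np.arange(n_groups), n_per)
        effects = rng.normal(0, 1.5, n_groups)
        y = 2.0 + effects[g] + rng.normal(0, 1.0, g.size)
        X = np.ones((g.size, 1))
        design = RandomEffectDesign([build_group_design(g)])
        fit = fit_gaussian_mem_reml(y, np.ones(g.size), X, design)
        gm = np.array([y[g == i].mean() for i in range(n_groups)])
        msa = n_per * np.sum((gm - y.mean()) ** 2) / (n_groups - 1)
        mse = sum(((y[g == i] - gm[i]) ** 2).sum() for i in range(n_groups)) \
            / (g.size - n_groups)
        assert msa > mse  # interior optimum
        assert fit.tau2[0] == pytest.approx((msa - mse) / n_per, rel=1e-4)
        assert fit.scale == pytest.approx(mse, rel=1e-4)

    def test_penalized_wls_against_brute_normal_equations(self, rng):
        for _ in range(10):
            n, p, m = 25, 2, 4
            Xt = rng.standard_normal((n, p + m))
            y = rng.standard_normal(n)
            w = rng.uniform(0.5, 2.0, n)
            pen = np.r_[np.zeros(p), rng.uniform(0.1, 3.0, m)]
            beta, _, edof = _penalized_wls(Xt, y, w, pen)
            a = (Xt.T * w) @ Xt + np.diag(pen)
            oracle = np.linalg.solve(a, (Xt.T * w) @ y)
            np.testing.assert_allclose(beta, oracle, atol=1e-10)
            assert edof == pytest.approx(
                np.trace(np.linalg.solve(a, (Xt.T * w) @ Xt)), abs=1e-8)

    def test_edof_monotone_in_penalty(self, rng):
        n = 30
        Xt = np.column_stack([np.ones(n), rng.standard_normal((n, 5))])
        y = rng.standard_normal(n)
        w = np.ones(n)
        edofs = []
        for lam in [0.0, 0.1, 1.0, 10.0, 1e4]:
            pen = np.r_[0.0, np.full(5, lam)]
            _, _, edof = _penalized_wls(Xt, y, w, pen)
            edofs.append(edof)
        assert edofs[0] == pytest.approx(6.0, abs=1e-8)  # zero penalty: all cols
        assert np.all(np.diff(edofs) < 0)
        assert edofs[-1] > 1.0 - 1e-8  # fixed column never penalized away


class TestProposedMEM:
    def test_empty_design_reduces_to_fixed_effects(self, rng):
        d = make_dataset(rng, n=60, sigma2=3.0)
        fx = fit_proposed(d)
        mx = fit_mem_proposed(d, RandomEffectDesign())
        np.testing.assert_array_equal(mx.beta, fx.beta)
        np.testing.assert_array_equal(mx.cov_beta, fx.cov_beta)
        assert mx.sigma2 == fx.sigma2
        assert mx.edof == d.k

    def test_zero_prior_precision_reduces_to_fixed_normal_equations(self, rng):
        """With Sigma_beta^-1 = 0 the penalized estimators collapse to the
        plain weighted normal equations over all columns."""
        n = 40
        Xt = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        lam = rng.uniform(0.5, 5.0, n)
        t = rng.standard_normal(n)
        beta, _, edof = _penalized_wls(Xt, t, lam, np.zeros(4))
        sw = np.sqrt(lam)
        oracle, *_ = np.linalg.lstsq(Xt * sw[:, None], t * sw, rcond=None)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)
        assert edof == pytest.approx(4.0, abs=1e-9)

    def test_spatial_recovery_comparable_to_step_one(self, rng):
        """Step-II field recovery stays close to the step-I Gaussian fit
        (the plug-in should not degrade the spatial estimate)."""
        from lgpois import (ScenarioConfig, SpatialConfig, build_scenario,
                            proposed_transform, zero_ratio)
        cfg = ScenarioConfig(n=120, beta0=0.0, sigma2=5.0,
                             spatial=SpatialConfig(scale=1.0), seed=77,
                             n_iter=1)
        ds, truth = next(build_scenario(cfg))
        design = RandomEffectDesign([build_lowrank_gp_basis(ds.coords)])
        fit = fit_mem_proposed(ds, design)
        s_hat = fit.random_effect_predictions["spatial"]
        rmse2 = np.sqrt(np.mean((s_hat - truth["s"]) ** 2))

        tr = proposed_transform(ds.y, ds.z, zero_ratio(ds.y))
        g = fit_gaussian_mem_reml(tr.log_yplus, tr.weights, ds.X, design)
        sl = dict(design.slices(offset=g.n_fixed))["spatial"]
        s_step1 = design.blocks[0].Z @ g.beta[sl]
        rmse1 = np.sqrt(np.mean((s_step1 - truth["s"]) ** 2))
        assert abs(rmse2 - rmse1) / rmse1 < 0.3
        assert np.all(np.isfinite(fit.beta))
        assert fit.sigma2 > 0

    def test_never_diverges_on_many_zero_spatial_data(self, rng):
        from lgpois import ScenarioConfig, SpatialConfig, build_scenario
        cfg = ScenarioConfig(n=50, beta0=-2.0, sigma2=5.0,
                             spatial=SpatialConfig(scale=1.0), seed=13,
                             n_iter=5)
        for ds, _ in build_scenario(cfg):
            design = RandomEffectDesign([build_lowrank_gp_basis(ds.coords)])
            fit = fit_mem_proposed(ds, design)
            assert np.all(np.isfinite(fit.beta))


class TestComparatorMEM:
    def test_taylor_no_blocks_reduces_to_fixed_comparator(self, rng):
        d = make_dataset(rng, n=60)
        fx = fit_comparator(d, "taylor", 0.5)
        mx = fit_mem_comparators(d, RandomEffectDesign(), method="taylor")
        np.testing.assert_array_equal(mx.beta, fx.beta)
        assert mx.sigma2 == fx.sigma2

    def test_unknown_method_rejected(self, rng):
        d = make_dataset(rng, n=30)
        with pytest.raises(InvalidInputError):
            fit_mem_comparators(d, RandomEffectDesign(), method="negbin")

    def test_poisson_mem_near_mle_when_random_effects_weak(self, rng):
        from lgpois import ScenarioConfig, SpatialConfig, build_scenario
        cfg = ScenarioConfig(n=150, beta0=2.0, beta=(0.5, 0.3), sigma2=1.0,
                             spatial=SpatialConfig(scale=0.05), seed=5,
                             n_iter=1)
        ds, _ = next(build_scenario(cfg))
        design = RandomEffectDesign([build_lowrank_gp_basis(ds.coords)])
        mx = fit_mem_comparators(ds, design, method="poisson")
        mle = fit_irls_poisson(ds)
        np.testing.assert_allclose(mx.beta[:3], mle.beta, atol=0.05)

    def test_odpoisson_dispersion_near_one_without_overdispersion(self, rng):
        from lgpois import ScenarioConfig, SpatialConfig, build_scenario
        cfg = ScenarioConfig(n=200, beta0=1.0, sigma2=1.0,
                             spatial=SpatialConfig(scale=0.5), seed=21,
                             n_iter=10)
        vals = []
        for ds, _ in build_scenario(cfg):
            design = RandomEffectDesign([build_lowrank_gp_basis(ds.coords)])
            vals.append(fit_mem_comparators(ds, design, method="odpoisson").sigma2)
        assert 0.7 <= np.mean(vals) <= 1.4
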