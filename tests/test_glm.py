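"""Fixed-effects estimators: hand-derived values, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from lgpois import (CountDataset, DivergenceError, fit_comparator,
                    fit_irls_poisson, fit_negbin, fit_proposed)
from conftest import make_dataset


def intercept_only(y):
    y = np.asarray(y, dtype=float)
    return CountDataset(y=y, X=np.ones((y.size, 1)))


class TestIrlsPoisson:
    def test_intercept_only_is_sample_mean(self):
        fit = fit_irls_poisson(intercept_only([2, 2, 2]))
        assert fit.beta[0] == pytest.approx(np.log(2), abs=1e-10)
        np.testing.assert_allclose(fit.lambda_hat, 2.0, atol=1e-9)

    def test_dispersion_hand_value(self):
        # lam = 2, sigma2 = ((0-2)^2/2 + (4-2)^2/2) / (2-1) = 4
        fit = fit_irls_poisson(intercept_only([0, 4]), overdispersed=True)
        np.testing.assert_allclose(fit.lambda_hat, 2.0, atol=1e-9)
        assert fit.sigma2 == pytest.approx(4.0, abs=1e-8)

    def test_pure_poisson_sigma2_is_one(self, small_poisson_dataset):
        fit = fit_irls_poisson(small_poisson_dataset, overdispersed=False)
        assert fit.sigma2 == 1.0

    def test_matches_direct_likelihood_maximization(self, small_poisson_dataset):
        """IRLS solution agrees with an independent optimizer of the
        Poisson log-likelihood and with the statsmodels GLM fit."""
        d = small_poisson_dataset
        fit = fit_irls_poisson(d)

        def nll(beta):
            eta = d.X @ beta
            return float(np.sum(np.exp(eta)) - d.y @ eta)

        res = minimize(nll, np.zeros(d.k), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-4)

        import statsmodels.api as sm
        glm = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)

    def test_point_estimates_identical_and_covariance_scales(self,
                                                             small_poisson_dataset):
        plain = fit_irls_poisson(small_poisson_dataset, overdispersed=False)
        od = fit_irls_poisson(small_poisson_dataset, overdispersed=True)
        np.testing.assert_array_equal(plain.beta, od.beta)
        np.testing.assert_array_equal(plain.lambda_hat, od.lambda_hat)
        np.testing.assert_allclose(od.cov_beta, od.sigma2 * plain.cov_beta,
                                   rtol=1e-12)

    def test_all_zero_counts_diverge(self):
        with pytest.raises(DivergenceError) as exc:
            fit_irls_poisson(intercept_only([0, 0, 0, 0]))
        assert exc.value.last_iterate is not None

    def test_lambda_equals_offset_times_exp_mu(self, rng):
        d = make_dataset(rng, n=40, offset=rng.uniform(0.5, 3.0, 40))
        fit = fit_irls_poisson(d)
        np.testing.assert_allclose(fit.lambda_hat, d.z * np.exp(fit.mu_hat),
                                   rtol=1e-12)


class TestProposed:
    def test_hand_evaluation_both_steps(self):
        # step I: mu+ = log(2.5) - 1/2.5; step II: beta = mu+ + (2-lam+)/lam+
        fit = fit_proposed(intercept_only([2, 2, 2]))
        mu_plus = np.log(2.5) - 1 / 2.5
        lam_plus = np.exp(mu_plus)
        assert fit.info["beta_plus"][0] == pytest.approx(mu_plus, abs=1e-12)
        assert fit.beta[0] == pytest.approx(mu_plus + (2 - lam_plus) / lam_plus,
                                            abs=1e-10)
        assert fit.beta[0] == pytest.approx(0.70975, abs=1e-5)

    def test_agrees_with_mle_for_large_counts(self, rng):
        d = make_dataset(rng, n=300, beta=(5.0, 0.25))
        assert d.y.min() >= 50
        mle = fit_irls_poisson(d)
        prop = fit_proposed(d)
        np.testing.assert_allclose(prop.beta, mle.beta, atol=0.02)

    def test_offset_doubling_shifts_only_intercept(self, rng):
        d = make_dataset(rng, n=60)
        d2 = CountDataset(y=d.y, X=d.X, z=2 * d.z)
        f1, f2 = fit_proposed(d), fit_proposed(d2)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(2), abs=1e-10)
        np.testing.assert_allclose(f1.beta[1:], f2.beta[1:], atol=1e-10)

    def test_step_one_matches_wls_normal_equations(self, rng):
        """Step-I solution equals the generic (X'WX)^-1 X'W log(y+)."""
        from lgpois import proposed_transform, zero_ratio
        d = make_dataset(rng, n=30)
        tr = proposed_transform(d.y, d.z, zero_ratio(d.y))
        sw = np.sqrt(tr.weights)
        oracle, *_ = np.linalg.lstsq(d.X * sw[:, None], tr.log_yplus * sw,
                                     rcond=None)
        fit = fit_proposed(d)
        np.testing.assert_allclose(fit.info["beta_plus"], oracle, atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_never_diverges_on_many_zero_data(self, seed):
        """The two-step estimator is closed-form and stays finite even on
        data where Poisson IRLS diverges."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        x = rng.standard_normal(n)
        lam = np.exp(-2.5 + 2.0 * x)
        y = rng.poisson(lam)
        d = CountDataset(y=y, X=np.column_stack([np.ones(n), x]))
        fit = fit_proposed(d)
        assert np.all(np.isfinite(fit.beta))
        assert np.all(np.isfinite(fit.cov_beta))


class TestComparators:
    def test_intercept_only_hand_values(self):
        d = intercept_only([2, 2, 2])
        assert fit_comparator(d, "loglinear", 0.5).beta[0] == pytest.approx(
            np.log(2.5), abs=1e-12)
        assert fit_comparator(d, "taylor", 0.5).beta[0] == pytest.approx(
            np.log(2.5) - 0.5 / 2.5, abs=1e-12)

    def test_equal_weights_reduce_to_ols(self, rng):
        # equal counts => equal weights => WLS == OLS
        y = np.full(25, 3)
        X = np.column_stack([np.ones(25), rng.standard_normal(25)])
        d = CountDataset(y=y, X=X)
        fit = fit_comparator(d, "loglinear", 0.5)
        from lgpois import comparator_transform
        resp = comparator_transform(y, 0.5, "loglinear").log_yplus
        ols, *_ = np.linalg.lstsq(X, resp, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-10)


class TestNegbin:
    def test_intercept_only_mean(self, rng):
        y = rng.poisson(4.0, 200)
        fit = fit_negbin(CountDataset(y=y, X=np.ones((200, 1))))
        assert fit.lambda_hat[0] == pytest.approx(y.mean(), rel=1e-4)

    def test_alpha_recovery(self, rng):
        # NB2 with alpha = 0.5: sigma2 = 5, lambda = 5 => nu = 4/5... use
        # the gamma-Poisson generator at matching dispersion
        n = 2000
        lam = np.full(n, 5.0)
        from lgpois import gen_odpoisson
        y = gen_odpoisson(lam, sigma2=1 + 0.5 * 5.0, seed=rng)
        fit = fit_negbin(CountDataset(y=y, X=np.ones((n, 1))))
        assert fit.info["alpha"] == pytest.approx(0.5, abs=0.1)

    def test_poisson_boundary(self, rng):
        d = make_dataset(rng, n=400, sigma2=1.0)
        nb = fit_negbin(d)
        mle = fit_irls_poisson(d)
        assert nb.info["alpha"] < 0.05
        np.testing.assert_allclose(nb.beta, mle.beta, atol=0.02)
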