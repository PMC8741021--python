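"""Fixed-effects estimators for count regression.

Four families, all returning a :class:`FixedFit`:

* ``fit_irls_poisson`` — Poisson maximum likelihood by IRLS; with
  ``overdispersed=True`` the coefficient covariance is scaled by the
  moment estimator of the dispersion sigma^2 (quasi-Poisson).  The point
  estimates are identical either way.
* ``fit_proposed`` — the two-step plug-in estimator: (I) weighted least
  squares of the mode-matched log-Gaussian response on X, giving a
  stable mean estimate lambda+; (II) one closed-form evaluation of the
  IRLS normal equations at lambda+ (no iteration), giving coefficients,
  dispersion and covariance.  Step I cannot diverge, so the estimator is
  free of the Poisson identification failure.
* ``fit_comparator`` — plain weighted Gaussian regression on the
  log-linear or Taylor transform (the classical closed-form recipes).
* ``fit_negbin`` — NB2 negative binomial maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data import CountDataset
from .exceptions import ConvergenceError, DivergenceError, InvalidInputError
from .transforms import comparator_transform, proposed_transform, zero_ratio

__all__ = [
    "FixedFit",
    "fit_irls_poisson",
    "fit_proposed",
    "fit_comparator",
    "fit_negbin",
]

#: floor applied to fitted means in divisions so degenerate fits stay finite
LAMBDA_FLOOR = 1e-10

#: coefficient magnitude beyond which IRLS is declared divergent
BETA_BOUND = 30.0


@dataclass
class FixedFit:
    """Result of a fixed-effects count regression.

    ``lambda_hat = z * exp(mu_hat)`` always holds; ``sigma2`` is 1
    exactly for the pure Poisson fit.  ``info`` carries method-specific
    extras (e.g. the step-I quantities of the proposed estimator, or the
    NB2 overdispersion alpha).
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    lambda_hat: np.ndarray
    mu_hat: np.ndarray
    method: str
    converged: bool = True
    n_iter: int = 0
    info: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        """Coefficient standard errors."""
        return np.sqrt(np.diag(self.cov_beta))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve the weighted normal equations (X'WX) b = X'W y."""
    xtw = X.T * w
    a = xtw @ X
    b = xtw @ y
    try:
        return scipy.linalg.solve(a, b, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"weighted design is singular: {exc}") from exc


def _dispersion(y: np.ndarray, lam: np.ndarray, dof: float) -> float:
    """Moment estimator of sigma^2: sum((y - lam)^2 / lam) / dof."""
    lam = np.maximum(lam, LAMBDA_FLOOR)
    return float(np.sum((y - lam) ** 2 / lam) / dof)


def fit_irls_poisson(data: CountDataset, overdispersed: bool = True,
                     max_iter: int = 100, tol: float = 1e-8) -> FixedFit:
    """Poisson / over-dispersed Poisson regression by IRLS.

    Alternates the weighted least-squares update
    ``beta = (X' L X)^-1 X' L t`` with working response
    ``t_i = mu_i + (y_i - lam_i)/lam_i`` and mean update
    ``lam_i = z_i exp(mu_i)`` until the coefficients stabilize.

    Raises
    ------
    DivergenceError
        If any coefficient exceeds ``BETA_BOUND`` in magnitude — the
    observable form of the identification failure with many zeros.
    ConvergenceError
        If ``max_iter`` is reached without convergence.
    """
    y, z, X = data.y, data.z, data.X
    n, k = data.n, data.k
    if n <= k:
        raise InvalidInputError("need more observations than covariates")
    mu = np.log((y + 0.5) / z)
    beta = _wls(X, mu, np.ones(n))
    for it in range(1, max_iter + 1):
        mu = X @ beta
        lam = np.maximum(z * np.exp(mu), LAMBDA_FLOOR)
        t = mu + (y - lam) / lam
        new_beta = _wls(X, t, lam)
        if np.any(np.abs(new_beta) > BETA_BOUND):
            raise DivergenceError(
                "IRLS coefficients diverged (identification failure)",
                last_iterate=new_beta, n_iter=it,
            )
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations",
            last_iterate=beta, n_iter=max_iter,
        )
    mu = X @ beta
    lam = z * np.exp(mu)
    sigma2 = _dispersion(y, lam, n - k) if overdispersed else 1.0
    xtlx = (X.T * np.maximum(lam, LAMBDA_FLOOR)) @ X
    cov = sigma2 * np.linalg.inv(xtlx)
    return FixedFit(
        beta=beta, cov_beta=cov, sigma2=sigma2, lambda_hat=lam, mu_hat=mu,
        method="odpoisson" if overdispersed else "poisson",
        converged=True, n_iter=it,
    )


def fit_proposed(data: CountDataset) -> FixedFit:
    """Two-step mode-matched log-Gaussian plug-in estimator.

    Step I regresses ``log(y+)`` on X with weights ``y + 0.5`` (a single
    WLS solve) to obtain ``mu+`` and the stable mean estimate
    ``lam+ = z exp(mu+)``.  Step II evaluates the IRLS normal equations
    once at ``lam+`` — working response ``mu+ + (y - lam+)/lam+`` — and
    plugs ``lam+`` into the dispersion and covariance formulas.
    """
    y, z, X = data.y, data.z, data.X
    n, k = data.n, data.k
    if n <= k:
        raise InvalidInputError("need more observations than covariates")
    r = zero_ratio(y)
    tr = proposed_transform(y, z, r)
    beta_plus = _wls(X, tr.log_yplus, tr.weights)
    mu_plus = X @ beta_plus
    lam_plus = np.maximum(z * np.exp(mu_plus), LAMBDA_FLOOR)

    t = mu_plus + (y - lam_plus) / lam_plus
    beta = _wls(X, t, lam_plus)
    sigma2 = _dispersion(y, lam_plus, n - k)
    cov = sigma2 * np.linalg.inv((X.T * lam_plus) @ X)
    mu = X @ beta
    return FixedFit(
        beta=beta, cov_beta=cov, sigma2=sigma2,
        lambda_hat=z * np.exp(mu), mu_hat=mu, method="proposed",
        converged=True, n_iter=1,
        info={"r": r, "beta_plus": beta_plus, "lambda_plus": lam_plus},
    )


def fit_comparator(data: CountDataset, method: str = "loglinear",
                   c: float = 0.5) -> FixedFit:
    """Weighted Gaussian regression on a classical log transform.

    Coefficients and covariance come straight from the WLS fit of the
    transformed response (no Poisson step); ``sigma2`` is the weighted
    residual variance of that Gaussian model.
    """
    y, z, X = data.y, data.z, data.X
    n, k = data.n, data.k
    if n <= k:
        raise InvalidInputError("need more observations than covariates")
    tr = comparator_transform(y, c=c, method=method, z=z)
    beta = _wls(X, tr.log_yplus, tr.weights)
    resid = tr.log_yplus - X @ beta
    sigma2 = float(np.sum(tr.weights * resid**2) / (n - k))
    cov = sigma2 * np.linalg.inv((X.T * tr.weights) @ X)
    mu = X @ beta
    return FixedFit(
        beta=beta, cov_beta=cov, sigma2=sigma2,
        lambda_hat=z * np.exp(mu), mu_hat=mu, method=method,
        converged=True, n_iter=1, info={"c": c, "r": tr.r},
    )


def fit_negbin(data: CountDataset, max_iter: int = 200) -> FixedFit:
    """NB2 negative binomial regression (Var[Y] = lam + alpha lam^2).

    The reported ``sigma2`` is the dispersion implied at the average
    fitted mean, ``1 + alpha * mean(lambda_hat)``, so it is comparable
    with the quasi-Poisson sigma^2.
    """
    import statsmodels.api as sm

    y, z, X = data.y, data.z, data.X
    n, k = data.n, data.k
    if n <= k:
        raise InvalidInputError("need more observations than covariates")
    model = sm.NegativeBinomial(y, X, offset=np.log(z), loglike_method="nb2")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=max_iter)
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            raise ConvergenceError(f"negative binomial fit failed: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", True))
    # alpha pinned at the lower boundary (pure Poisson) trips the
    # optimizer's convergence flag; report it as Poisson-equivalent
    at_boundary = float(res.params[-1]) < 1e-4 and np.all(np.isfinite(res.params))
    if not converged and not at_boundary:
        raise ConvergenceError(
            "negative binomial fit did not converge",
            last_iterate=res.params, n_iter=max_iter,
        )
    beta = np.asarray(res.params[:k])
    if np.any(np.abs(beta) > BETA_BOUND):
        raise DivergenceError(
            "negative binomial coefficients diverged", last_iterate=beta
        )
    alpha = max(float(res.params[-1]), 0.0)
    try:
        cov = np.asarray(res.cov_params())[:k, :k]
    except ValueError as exc:
        # singular/unavailable Hessian at a degenerate optimum
        raise ConvergenceError(
            f"negative binomial covariance unavailable: {exc}",
            last_iterate=res.params,
        ) from exc
    mu = X @ beta
    lam = z * np.exp(mu)
    return FixedFit(
        beta=beta, cov_beta=cov, sigma2=1.0 + alpha * float(np.mean(lam)),
        lambda_hat=lam, mu_hat=mu, method="negbin",
        converged=True, n_iter=int(res.mle_retvals.get("iterations", 0) or 0),
        info={"alpha": alpha},
    )
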