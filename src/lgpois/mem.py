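"""Poisson additive mixed models via the mode-matched approximation.

A mixed / additive model here is ``lambda_i = z_i exp(x_i' b + sum_l
u_{i,l})`` where each random term ``u_l`` is either a group-wise random
intercept (iid N(0, tau_l^2) per level) or a low-rank Gaussian process
over planar coordinates with exponentially decaying covariance
``C_ij = exp(-d_ij / h)``, represented in its truncated eigenbasis
(predictive-process style).

Estimators:

* ``fit_gaussian_mem_reml`` — the Gaussian working-model engine:
  restricted (or full) maximum likelihood over the variance components
  of ``y ~ N(X b + Z u, phi W^-1)``, with penalized-WLS coefficients and
  the effective degrees of freedom at the optimum.
* ``fit_mem_proposed`` — step I fits the Gaussian MEM to the
  mode-matched response log(y+) with weights y + 0.5; step II is one
  closed-form evaluation of the penalized IRLS normal equations at the
  resulting mean estimate lambda+ (no iteration, so no divergence).
* ``fit_mem_comparators`` — PQL-style penalized IRLS for the Poisson /
  over-dispersed Poisson MEM, and the Taylor-transform Gaussian MEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .data import CountDataset
from .exceptions import ConvergenceError, DivergenceError, InvalidInputError
from .glm import BETA_BOUND, LAMBDA_FLOOR, FixedFit, _dispersion, fit_proposed
from .transforms import comparator_transform, proposed_transform, zero_ratio

__all__ = [
    "RandomEffectBlock",
    "RandomEffectDesign",
    "build_group_design",
    "build_lowrank_gp_basis",
    "GaussianMEMFit",
    "fit_gaussian_mem_reml",
    "MixedFit",
    "fit_mem_proposed",
    "fit_mem_comparators",
]

#: lower bound for variance components, keeps prior precisions finite
TAU2_FLOOR = 1e-10


@dataclass
class RandomEffectBlock:
    """One random-effect term: an N x m basis with prior tau^2 * I."""

    name: str
    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[1] < 1:
            raise InvalidInputError(f"block {self.name!r} has no columns")
        if np.any(np.all(self.Z == 0, axis=0)):
            raise InvalidInputError(f"block {self.name!r} has an all-zero column")

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class RandomEffectDesign:
    """Ordered collection of random-effect blocks."""

    blocks: list[RandomEffectBlock] = field(default_factory=list)

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)

    @property
    def ncols(self) -> int:
        return sum(b.m for b in self.blocks)

    def matrix(self, n: int) -> np.ndarray:
        """Concatenated N x (sum m_l) random-effect basis."""
        if not self.blocks:
            return np.zeros((n, 0))
        for b in self.blocks:
            if b.Z.shape[0] != n:
                raise InvalidInputError(
                    f"block {b.name!r} has {b.Z.shape[0]} rows, expected {n}"
                )
        return np.hstack([b.Z for b in self.blocks])

    def slices(self, offset: int = 0) -> list[tuple[str, slice]]:
        """(name, column slice) pairs, optionally shifted by ``offset``."""
        out, pos = [], offset
        for b in self.blocks:
            out.append((b.name, slice(pos, pos + b.m)))
            pos += b.m
        return out


def build_group_design(labels, name: str = "group") -> RandomEffectBlock:
    """Indicator block for a group-wise random intercept.

    One column per distinct level (sorted), exactly one 1 per row; the
    implied prior is tau^2 * I over level effects.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise InvalidInputError("labels must be a non-empty 1-D vector")
    levels, codes = np.unique(labels, return_inverse=True)
    if levels.size < 2:
        raise InvalidInputError("need at least 2 distinct group levels")
    Z = np.zeros((labels.size, levels.size))
    Z[np.arange(labels.size), codes] = 1.0
    return RandomEffectBlock(name=name, Z=Z)


def build_lowrank_gp_basis(coords, rank: int | None = None,
                           range_h: float | None = None,
                           name: str = "spatial") -> RandomEffectBlock:
    """Truncated eigenbasis of an exponential-decay spatial kernel.

    Builds ``C_ij = exp(-d_ij / h)`` on the Euclidean distances between
    coordinates, eigendecomposes, and returns the basis
    ``E_m diag(sqrt(eig_m))`` from the top-m eigenpairs.  With prior
    tau^2 * I on the basis coefficients the implied process covariance is
    tau^2 times the rank-m truncation of C.

    Defaults: ``rank = min(50, N)``; ``range_h`` = median inter-point
    distance.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InvalidInputError("coords must be an N x 2 array")
    if not np.all(np.isfinite(coords)):
        raise InvalidInputError("coords must be finite")
    n = coords.shape[0]
    if rank is None:
        rank = min(50, n)
    if rank < 1 or rank > n:
        raise InvalidInputError(f"rank must be in [1, N], got {rank}")
    d = pdist(coords)
    if range_h is None:
        positive = d[d > 0]
        if positive.size == 0:
            raise InvalidInputError("all points coincide; specify range_h")
        range_h = float(np.median(positive))
    if range_h <= 0:
        raise InvalidInputError("range_h must be positive")
    kernel = np.exp(-squareform(d) / range_h)
    eigval, eigvec = scipy.linalg.eigh(kernel)
    order = np.argsort(eigval)[::-1][:rank]
    eigval = np.clip(eigval[order], 0.0, None)
    basis = eigvec[:, order] * np.sqrt(eigval)
    return RandomEffectBlock(name=name, Z=basis)


@dataclass
class GaussianMEMFit:
    """Gaussian mixed-model fit on a working response.

    ``beta`` spans fixed then random columns; ``tau2`` is per block;
    ``scale`` is the residual scale phi (variance of an observation with
    unit weight); ``edof`` the trace of the penalized hat matrix.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: np.ndarray
    scale: float
    edof: float
    mu: np.ndarray
    n_fixed: int
    converged: bool = True


def _penalized_wls(Xt, y, w, penalty_diag):
    """Solve (Xt'W Xt + P) b = Xt'W y; returns (b, A_inv, hat trace)."""
    xtw = Xt.T * w
    a = xtw @ Xt + np.diag(penalty_diag)
    try:
        a_inv = scipy.linalg.inv(a)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"penalized design is singular: {exc}") from exc
    b = a_inv @ (xtw @ y)
    edof = float(np.trace(a_inv @ (xtw @ Xt)))
    return b, a_inv, edof


def fit_gaussian_mem_reml(response, weights, X, design: RandomEffectDesign,
                          method: str = "reml", fix_scale: float | None = None,
                          theta0=None) -> GaussianMEMFit:
    """REML (or ML) fit of ``y ~ N(X b + Z u, phi W^-1)``, ``u_l ~ N(0, tau_l^2 I)``.

    Variance parameters are optimized on the log scale with lower bound
    ``TAU2_FLOOR``; ``fix_scale`` pins phi (e.g. to 1 for a Poisson
    working model).  Coefficients are the penalized-WLS solution at the
    optimum; ``edof`` is the trace of the hat-type matrix over all
    columns (fixed columns are unpenalized).

    Raises ``ConvergenceError`` if the optimizer fails.
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,) or w.shape != (n,):
        raise InvalidInputError("response, weights and X have inconsistent shapes")
    if np.any(w <= 0):
        raise InvalidInputError("weights must be positive")
    if method not in ("reml", "ml"):
        raise InvalidInputError("method must be 'reml' or 'ml'")
    nblocks = len(design)

    if nblocks == 0:
        from .glm import _wls

        beta = _wls(X, y, w)
        resid = y - X @ beta
        if fix_scale is not None:
            phi = float(fix_scale)
        else:
            phi = float(np.sum(w * resid**2) / max(n - p, 1))
        cov = phi * scipy.linalg.inv((X.T * w) @ X)
        return GaussianMEMFit(
            beta=beta, cov_beta=cov, tau2=np.zeros(0), scale=phi,
            edof=float(p), mu=X @ beta, n_fixed=p,
        )

    Z = design.matrix(n)
    zzt = [b.Z @ b.Z.T for b in design]
    w_inv = 1.0 / w

    from .glm import _wls

    beta0_wls = _wls(X, y, w)
    resid0 = y - X @ beta0_wls
    if np.max(np.abs(resid0)) <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        # response lies exactly in the fixed-effect span: no residual
        # variation for either the noise or the random effects to absorb
        total = p + design.ncols
        beta = np.r_[beta0_wls, np.zeros(design.ncols)]
        return GaussianMEMFit(
            beta=beta, cov_beta=np.zeros((total, total)),
            tau2=np.zeros(nblocks), scale=0.0, edof=float(p),
            mu=X @ beta0_wls, n_fixed=p,
        )

    estimate_phi = fix_scale is None

    def unpack(theta):
        tau2 = np.exp(theta[:nblocks])
        phi = np.exp(theta[nblocks]) if estimate_phi else float(fix_scale)
        return tau2, phi

    def neg2(theta):
        tau2, phi = unpack(theta)
        v = np.diag(phi * w_inv)
        for t2, zz in zip(tau2, zzt):
            v += t2 * zz
        try:
            cho = scipy.linalg.cho_factor(v, lower=True)
        except scipy.linalg.LinAlgError:
            return 1e12
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        vinv_x = scipy.linalg.cho_solve(cho, X)
        vinv_y = scipy.linalg.cho_solve(cho, y)
        xtvx = X.T @ vinv_x
        xtvy = X.T @ vinv_y
        try:
            beta_gls = scipy.linalg.solve(xtvx, xtvy, assume_a="pos")
        except scipy.linalg.LinAlgError:
            return 1e12
        quad = float(y @ vinv_y - xtvy @ beta_gls)
        out = logdet_v + quad
        if method == "reml":
            sign, logdet_xtvx = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return 1e12
            out += logdet_xtvx
        return out

    if theta0 is None:
        from .glm import _wls

        resid0 = y - X @ _wls(X, y, w)
        phi0 = max(float(np.sum(w * resid0**2) / max(n - p, 1)), 1e-4)
        theta0 = np.log(np.r_[np.full(nblocks, max(phi0, 1e-2)),
                              [phi0] if estimate_phi else []])
    else:
        theta0 = np.asarray(theta0, dtype=float)

    ndim = nblocks + (1 if estimate_phi else 0)
    bounds = [(np.log(TAU2_FLOOR), np.log(1e8))] * nblocks
    if estimate_phi:
        bounds.append((np.log(1e-12), np.log(1e8)))
    res = minimize(neg2, theta0[:ndim], method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 200})
    if not np.all(np.isfinite(res.x)):
        raise ConvergenceError("variance-component optimization failed",
                               last_iterate=res.x)
    tau2, phi = unpack(res.x)

    Xt = np.hstack([X, Z])
    penalty = np.zeros(Xt.shape[1])
    pos = p
    for t2, block in zip(tau2, design):
        penalty[pos:pos + block.m] = phi / t2
        pos += block.m
    beta, a_inv, edof = _penalized_wls(Xt, y, w, penalty)
    return GaussianMEMFit(
        beta=beta, cov_beta=phi * a_inv, tau2=tau2, scale=phi, edof=edof,
        mu=Xt @ beta, n_fixed=p, converged=bool(res.success),
    )


@dataclass
class MixedFit(FixedFit):
    """Mixed-model fit: :class:`FixedFit` fields plus variance components.

    ``beta`` spans fixed then random-basis columns; ``tau2`` holds one
    variance component per random block; ``edof`` is the effective
    degrees of freedom L used in the dispersion denominator N - L;
    ``random_effect_predictions`` maps block name to the fitted N-vector
    of that effect.
    """

    tau2: np.ndarray = field(default_factory=lambda: np.zeros(0))
    edof: float = 0.0
    n_fixed: int = 0
    random_effect_predictions: dict = field(default_factory=dict)


def _predictions(design: RandomEffectDesign, beta: np.ndarray,
                 n_fixed: int) -> dict:
    out = {}
    for name, sl in design.slices(offset=n_fixed):
        block = next(b for b in design if b.name == name)
        out[name] = block.Z @ beta[sl]
    return out


def _sigma_inv_diag(design: RandomEffectDesign, tau2, n_fixed: int,
                    total: int) -> np.ndarray:
    """Prior precision diagonal blockdiag(0, I/tau2_l) over all columns."""
    d = np.zeros(total)
    pos = n_fixed
    for t2, block in zip(tau2, design):
        d[pos:pos + block.m] = 1.0 / max(t2, TAU2_FLOOR)
        pos += block.m
    return d


def fit_mem_proposed(data: CountDataset, design: RandomEffectDesign,
                     method: str = "reml") -> MixedFit:
    """Two-step plug-in estimator for the (over-dispersed) Poisson MEM.

    Step I: Gaussian MEM REML on log(y+) with weights y + 0.5 gives
    mu+ and lambda+ = z exp(mu+), plus the variance components tau^2.
    Step II: one penalized-WLS evaluation with precision lambda+ and the
    step-I prior — coefficients, covariance, effective degrees of
    freedom L and dispersion sum((y - lam+)^2 / lam+) / (N - L).

    With an empty design this reduces exactly to the fixed-effects
    two-step estimator.
    """
    if len(design) == 0:
        fx = fit_proposed(data)
        return MixedFit(
            beta=fx.beta, cov_beta=fx.cov_beta, sigma2=fx.sigma2,
            lambda_hat=fx.lambda_hat, mu_hat=fx.mu_hat, method="proposed",
            converged=True, n_iter=1, info=fx.info,
            tau2=np.zeros(0), edof=float(data.k), n_fixed=data.k,
        )
    y, z, X = data.y, data.z, data.X
    n = data.n
    r = zero_ratio(y)
    tr = proposed_transform(y, z, r)
    g = fit_gaussian_mem_reml(tr.log_yplus, tr.weights, X, design, method=method)
    Xt = np.hstack([X, design.matrix(n)])
    mu_plus = Xt @ g.beta
    lam_plus = np.maximum(z * np.exp(mu_plus), LAMBDA_FLOOR)

    t = mu_plus + (y - lam_plus) / lam_plus
    prior = _sigma_inv_diag(design, g.tau2, g.n_fixed, Xt.shape[1])
    beta, a_inv, edof = _penalized_wls(Xt, t, lam_plus, prior)
    sigma2 = _dispersion(y, lam_plus, n - edof)
    mu = Xt @ beta
    return MixedFit(
        beta=beta, cov_beta=sigma2 * a_inv, sigma2=sigma2,
        lambda_hat=z * np.exp(mu), mu_hat=mu, method="proposed",
        converged=g.converged, n_iter=1,
        info={"r": r, "lambda_plus": lam_plus, "scale_step1": g.scale},
        tau2=g.tau2, edof=edof, n_fixed=g.n_fixed,
        random_effect_predictions=_predictions(design, beta, g.n_fixed),
    )


def fit_mem_comparators(data: CountDataset, design: RandomEffectDesign,
                        method: str = "poisson", c: float = 0.5,
                        reml: str = "reml", max_outer: int = 50,
                        tol: float = 1e-6) -> MixedFit:
    """Comparator mixed-model estimators.

    ``taylor`` fits the Gaussian MEM to the Taylor transform with its
    weights y + c.  ``poisson`` / ``odpoisson`` run PQL-style penalized
    IRLS: the Gaussian MEM is re-fit (REML on the working response) each
    outer iteration; for ``poisson`` the working-model scale is pinned
    at 1, for ``odpoisson`` it is free and the final dispersion comes
    from the plug-in moment formula with denominator N - L.
    """
    y, z, X = data.y, data.z, data.X
    n = data.n
    if method == "taylor":
        if len(design) == 0:
            from .glm import fit_comparator

            fx = fit_comparator(data, method="taylor", c=c)
            return MixedFit(
                beta=fx.beta, cov_beta=fx.cov_beta, sigma2=fx.sigma2,
                lambda_hat=fx.lambda_hat, mu_hat=fx.mu_hat, method="taylor",
                converged=True, n_iter=1, info=fx.info,
                tau2=np.zeros(0), edof=float(data.k), n_fixed=data.k,
            )
        tr = comparator_transform(y, c=c, method="taylor", z=z)
        g = fit_gaussian_mem_reml(tr.log_yplus, tr.weights, X, design, method=reml)
        mu = g.mu
        return MixedFit(
            beta=g.beta, cov_beta=g.cov_beta, sigma2=g.scale,
            lambda_hat=z * np.exp(mu), mu_hat=mu, method="taylor",
            converged=g.converged, n_iter=1, info={"c": c},
            tau2=g.tau2, edof=g.edof, n_fixed=g.n_fixed,
            random_effect_predictions=_predictions(design, g.beta, g.n_fixed),
        )
    if method not in ("poisson", "odpoisson"):
        raise InvalidInputError(
            f"unknown MEM comparator {method!r}; expected poisson/odpoisson/taylor"
        )

    Xt = np.hstack([X, design.matrix(n)])
    eta = np.log((y + 0.5) / z)
    beta = None
    theta0 = None
    fix_scale = 1.0 if method == "poisson" else None
    g = None
    for it in range(1, max_outer + 1):
        lam = np.maximum(z * np.exp(np.clip(eta, -BETA_BOUND, BETA_BOUND)),
                         LAMBDA_FLOOR)
        t = eta + (y - lam) / lam
        g = fit_gaussian_mem_reml(t, lam, X, design, method=reml,
                                  fix_scale=fix_scale, theta0=theta0)
        if np.any(np.abs(g.beta[:g.n_fixed]) > BETA_BOUND):
            raise DivergenceError(
                "penalized IRLS coefficients diverged (identification failure)",
                last_iterate=g.beta, n_iter=it,
            )
        theta0 = np.log(np.r_[np.maximum(g.tau2, TAU2_FLOOR),
                              [g.scale] if fix_scale is None else []])
        delta = np.inf if beta is None else float(np.max(np.abs(g.beta - beta)))
        beta = g.beta
        eta = Xt @ beta
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {max_outer} iterations",
            last_iterate=beta, n_iter=max_outer,
        )
    lam = np.maximum(z * np.exp(eta), LAMBDA_FLOOR)
    prior = _sigma_inv_diag(design, g.tau2, g.n_fixed, Xt.shape[1])
    _, a_inv, edof = _penalized_wls(Xt, eta + (y - lam) / lam, lam, prior)
    sigma2 = _dispersion(y, lam, n - edof) if method == "odpoisson" else 1.0
    return MixedFit(
        beta=beta, cov_beta=sigma2 * a_inv, sigma2=sigma2,
        lambda_hat=lam, mu_hat=eta, method=method,
        converged=True, n_iter=it, info={},
        tau2=g.tau2, edof=edof, n_fixed=g.n_fixed,
        random_effect_predictions=_predictions(design, beta, g.n_fixed),
    )
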