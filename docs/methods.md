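# Methods

## Model

Counts `Y_i`, i = 1..N, follow an over-dispersed Poisson model:
`E[Y_i] = λ_i = z_i exp(μ_i)`, `Var[Y_i] = σ² λ_i` with `σ² ≥ 1`, offset
`z_i > 0` known. The linear predictor is `μ_i = x_i'β` for the fixed
model, plus random terms for the additive/mixed model:
group-wise intercepts `u_l ~ N(0, τ_l² I)` and/or a spatial process with
covariance `τ² exp(−d/h)` in Euclidean distance `d`, represented in the
truncated eigenbasis of the kernel (rank-m predictive-process form).

## The mode-matched transform

A log-Gaussian variable `y + c ~ LogN(μ_G, 1/(λ + c))` approximates the
Poisson count. The mode of `LogN(m, s²)` is `exp(m − s²)`; requiring it
to equal the Poisson mode center `λ − 0.5` pins the location to
`μ_G = log(λ − 0.5 + c) + 1/(λ + c)`. Only `c = 0.5` makes `μ_G` equal
to `log λ` plus the variance shift — i.e. an affine, unit-slope function
of the linear predictor for *every* λ — so the constant is not a tuning
knob but a consequence of mode matching
(`transforms.solve_mode_matching_constant` verifies this numerically;
the fitting path hard-codes 0.5).

The mode-based form is valid for λ ≥ 0.5; for λ < 0.5 the Poisson mode
is stuck at 0 and a mean-based rescaling (exponent 1.5 instead of 1 in
the correction term) is more faithful. Since λ is unknown, the two are
blended by the observed zero ratio `r` (an estimate of P(λ < 0.5)),
giving the single blended exponent `1 + 0.5 r` applied to every
observation — the blended formula is used as stated, not a
per-observation mixture. The unknown λ in the working variance is
replaced by the plug-in `y`, giving variance `1/(y + 0.5)` and hence
regression weight `y + 0.5`. `r` is computed once from the raw response
and never updated during fitting.

## Estimation

**Fixed effects (`glm.fit_proposed`).** Step I: WLS of `log(y⁺)` on X
with weights `y + 0.5` → `β̂⁺`, `λ̂⁺ = z exp(Xβ̂⁺)`. Step II: one
evaluation (never iterated) of the IRLS normal equations at `λ̂⁺` with
working response `μ̂⁺ + (y − λ̂⁺)/λ̂⁺`, dispersion
`σ̂² = Σ(y−λ̂⁺)²/λ̂⁺ / (N−K)` and covariance `σ̂²(X'Λ⁺X)⁻¹`. Both steps
are closed-form, so the estimator cannot diverge; this is what removes
the identification failure.

**Mixed models (`mem.fit_mem_proposed`).** Step I becomes a weighted
Gaussian mixed model estimated by REML (ML available via
`method="ml"`; REML is the default because the working-model variance
components feed the step-II penalty and REML is less biased). Step II is
the penalized analogue: `β̂ = (X̃'Λ⁺X̃ + Σ_β⁻¹)⁻¹ X̃'Λ⁺z⁺` with
`Σ_β⁻¹ = blockdiag(0, I/τ̂_1², …)` taken from step I without
re-estimation, effective degrees of freedom
`L = tr[(X̃'Λ⁺X̃ + Σ_β⁻¹)⁻¹ X̃'Λ⁺X̃]` over all columns, and
`σ̂²` with denominator `N − L`.

**REML engine.** The marginal covariance `V = φ W⁻¹ + Σ τ_l² Z_l Z_l'`
is formed densely (N×N Cholesky per objective evaluation — fine for the
N ≤ a few thousand this package targets); `−2ℓ_R = log|V| +
log|X'V⁻¹X| + y'Py` is minimized by L-BFGS-B over log-variance
parameters with bounds `τ² ≥ 1e−10` (keeps the prior precision finite;
a τ² at the bound is reported, not an error) and `φ` free or pinned.
The engine was cross-checked against the closed-form balanced one-way
REML estimators (in the test suite) and against R mgcv (agreement to
6 decimals on coefficients, τ², φ and effective dof). Responses lying
exactly in the fixed-effect span short-circuit to the WLS solution with
all τ² = 0.

**Comparators.** IRLS Poisson/quasi-Poisson: initialization
`μ = log((y+0.5)/z)`, convergence `max|Δβ| < 1e−8`, max 100 iterations,
divergence declared when any `|β_k| > 30` (makes the identification
failure an observable error instead of a hang); fitted means are floored
at 1e−10 inside divisions. σ̂² is not truncated below 1 — the moment
formula imposes no bound. Mixed-model Poisson/quasi-Poisson use
PQL-style penalized IRLS with a fresh REML solve of the working Gaussian
model each outer iteration (warm-started); numerical parity with mgcv's
outer-iteration scheme is not a goal. NB2 negative binomial is delegated
to statsmodels; an `α` pinned at the zero boundary is reported as
Poisson-equivalent rather than an error. Comparator transforms default
to `c = 0.5` (the value the mode-matching derivation forces; exposed as
an argument). Offsets enter all transforms uniformly as `−log z`.

## Synthetic data

`simulate` draws standard-normal covariates, slopes {2.0, 0.5} (one
strong, one weak), intercept grids {−2,…,2} (lower intercept → more
zeros), N ∈ {50, 200} and σ² ∈ {1, 5} by default. Over-dispersion uses
the gamma–Poisson construction with `ν_i = (σ²−1)/λ_i` (gamma shape
`1/ν_i`, mean `λ_i`), which matches the first two moments of the target
exactly; σ² = 1 is special-cased to pure Poisson draws (ν = 0 is
degenerate). Spatial scenarios place points uniformly on the unit
square (the spatial domain is not otherwise constrained by the
benchmark design) with field scale 1.0 by default — a field whose sd is
comparable to the strong covariate effect, a realistic
signal-to-noise for disease-mapping applications; basis rank defaults
to `min(50, N)` and kernel range to the median inter-point distance
(standard predictive-process practice). Group scenarios use 10 groups
with effect sd 1.0. Replication k uses seed `seed + k`, so runs are
bit-reproducible and any single replication can be regenerated.

What the generator does *not* emulate: temporal epidemic dynamics,
population-scale offsets with realistic heterogeneity, covariate
collinearity, or zero-inflation beyond what the odPoisson model itself
produces. A green Monte Carlo test therefore establishes estimator
behaviour under the stated model, not robustness to misspecification.

## Evaluation

`evaluate.run_experiment` fits each method to each replication and
summarizes RMSE and mean bias (averaging over the number of
replications), mean SE, and the calibration ratio
`mean(SE)/sd(estimates)`. Fits that diverge or error are excluded from
the summaries and surfaced as a per-method divergence rate, so accuracy
comparisons are explicitly conditional on convergence. Spatial scenarios
additionally report the mean over replications of
`sqrt(mean_i((ŝ_i − s_i)²))`. Default replication counts are desk-scale
(200 fixed / 100 spatial); the config accepts the full 1000/500 counts.

## Limitations

- The plug-in variance `1/(y + 0.5)` ignores estimation uncertainty in
  the working variance; SEs are mildly optimistic (visible in the
  calibration ratios, typically 0.8–1.1 in the tested regimes).
- The dense REML engine is O(N³) per objective evaluation; very large N
  needs a sparse/low-rank refactor.
- Only the exponential spatial kernel is provided (no Matérn,
  anisotropy, or tensor smooths), and only iid priors per random block.
- Dispersion estimates in rich mixed models are pulled toward 1 when
  the random terms absorb part of the over-dispersion; this is a
  property of the moment estimator with effective-dof denominator, not
  a bug.
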