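# lgpois

Closed-form inference for over-dispersed Poisson regression and Poisson
additive mixed models via a **mode-matched log-Gaussian approximation** —
fast, free of tuning constants, and free of the identification failure
that destabilizes Poisson maximum likelihood on small samples with many
zero counts.

## The problem

Count regressions `Y_i ~ odPoisson(λ_i, σ²)` with `λ_i = z_i exp(x_i'β)`
(mean `λ_i`, variance `σ²λ_i`, known offset `z_i`) are everywhere in
epidemiology and spatial surveillance. Poisson ML via IRLS has two known
pain points: for small samples with many zeros the MLE is weakly
identified and coefficient estimates can diverge, and for large additive
models the iterations are slow. The classical workaround — regress
`log(y + c)` with weight `y + c` in a Gaussian model — is closed-form
but biased for zero-heavy data, and the arbitrary constant `c`
materially changes the answer.

## The estimator

Matching the **mode** of an approximating log-Gaussian to the Poisson
mode center `λ − 0.5` forces `c = 0.5` (no free constant) and gives the
working response

```
log(y_i⁺) = log((y_i + 0.5)/z_i) − (1 + 0.5 r)/(y_i + 0.5),   weight y_i + 0.5,
```

where `r` is the fraction of zero counts: `r = 0` gives the pure
mode-based form (accurate for λ ≥ 0.5), `r = 1` the mean-based form
(accurate for λ < 0.5). Fitting proceeds in two steps:

1. **Step I** — weighted least squares (or a weighted Gaussian mixed
   model, REML) of `log(y⁺)` on the design gives a stable mean estimate
   `λ̂⁺ = z exp(μ̂⁺)`.
2. **Step II** — one closed-form evaluation of the (penalized) IRLS
   normal equations at `λ̂⁺` with working response
   `μ̂⁺ + (y − λ̂⁺)/λ̂⁺` yields `β̂`, `Var[β̂] = σ̂²(X'Λ⁺X + Σ_β⁻¹)⁻¹`, and
   `σ̂² = Σ(y_i − λ̂⁺_i)²/λ̂⁺_i / (N − L)` with `L` the effective degrees
   of freedom.

Random terms (group intercepts, low-rank spatial Gaussian processes
with exponential kernel) enter through the penalized design; comparator
estimators (IRLS Poisson / quasi-Poisson, NB2, log-linear and Taylor
transforms, PQL mixed models) and a seeded Monte Carlo harness are
included for benchmarking.

## Worked example

```python
import lgpois as lg

cfg = lg.ScenarioConfig(n=50, beta0=-2.0, sigma2=5.0, seed=3, n_iter=50)
res = lg.run_experiment(cfg, methods=["poisson", "odpoisson", "negbin",
                                      "loglinear", "taylor", "proposed"])
print(res.summary[res.summary.parameter == "beta1"]
      [["method", "rmse", "bias", "divergence_rate"]])
```

prints (50 replications of a many-zeros, over-dispersed design; true
slope 2.0):

```
   method  rmse   bias  divergence_rate
  poisson 1.350  0.443            0.000
odpoisson 1.350  0.443            0.000
   negbin 1.082  0.536            0.080
loglinear 1.027 -0.998            0.000
   taylor 0.758 -0.708            0.000
 proposed 0.520  0.197            0.000
```

The mode-matched estimator has the smallest RMSE, modest bias, and never
diverges; the classical transforms are stable but strongly biased, and
8% of NB2 fits fail outright. See `examples/` for more: the
mode-matching constant (`mode_matching.py`), single-dataset fits
(`fit_overdispersed.py`), spatial mixed models (`spatial_mem.py`), and a
CSV-to-JSON workflow (`fit_from_csv.py`).

## Acceptance script

`scripts/acceptance.py` re-derives the package's analytic headline
quantity from scratch: it solves the mode-matching linearity condition
numerically over a random grid of linear predictors and reports the
resulting constant. Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
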