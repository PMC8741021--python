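"""Small Monte Carlo comparison of estimator accuracy.

Replicates the many-zeros over-dispersed regime 50 times and tabulates
RMSE / bias of the strong slope plus the divergence rate per method.
(Scale n_iter up for publication-grade comparisons.)
"""

import lgpois as lg

cfg = lg.ScenarioConfig(n=50, beta0=-2.0, sigma2=5.0, seed=3, n_iter=50)
result = lg.run_experiment(cfg, methods=["poisson", "odpoisson", "negbin",
                                         "loglinear", "taylor", "proposed"])

summary = result.summary
b1 = summary[summary.parameter == "beta1"]
print("strong slope (true value 2.0), 50 replications:\n")
print(b1[["method", "rmse", "bias", "divergence_rate"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Low RMSE with zero divergence rate is the selling point of the
# closed-form approximation in this regime; the classical transforms
# (loglinear/taylor) are stable but biased, and likelihood-based fits
# can diverge.
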