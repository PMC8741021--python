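"""Monte Carlo experiment runner and accuracy metrics.

Replicates a scenario, fits a set of estimators to every replication,
and summarizes coefficient recovery by RMSE, mean bias, mean standard
error and the SE-accuracy ratio mean(SE) / sd(estimates) (near 1 when
the estimated standard errors track the true sampling variability).
Diverged or failed fits are excluded from the summaries and reported
through the per-method divergence rate, so comparisons are explicitly
conditional on convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm, mem
from .exceptions import InvalidInputError, LgpoisError
from .simulate import ScenarioConfig, build_scenario

__all__ = ["ExperimentResult", "rmse_bias", "se_ratio", "run_experiment",
           "FIXED_METHODS", "MIXED_METHODS"]

FIXED_METHODS = ("poisson", "odpoisson", "negbin", "loglinear", "taylor", "proposed")
MIXED_METHODS = ("poisson", "odpoisson", "taylor", "proposed")


def rmse_bias(estimates, truth: float) -> tuple[float, float]:
    """Root mean squared error and mean bias of replicated estimates.

    Both average over the number of estimates supplied:
    ``bias = mean(est - truth)``, ``rmse = sqrt(mean((est - truth)^2))``.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise InvalidInputError("need at least one estimate")
    err = est - float(truth)
    return float(np.sqrt(np.mean(err**2))), float(np.mean(err))


def se_ratio(ses, estimates) -> float:
    """mean(SE) / sd(estimates): the SE-calibration diagnostic.

    Values near 1 mean the estimated standard errors track the actual
    sampling spread; below 1 means the SEs are too small.
    """
    ses = np.asarray(ses, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise InvalidInputError("need at least two iterations")
    sd = float(np.std(est, ddof=1))
    if sd == 0:
        raise InvalidInputError("estimates are constant; SE ratio undefined")
    return float(np.mean(ses)) / sd


@dataclass
class ExperimentResult:
    """Per-iteration estimates and their summary for one scenario.

    ``per_iteration`` rows: (iteration, method, parameter, estimate, se,
    converged).  ``summary`` rows: (method, parameter, rmse, bias,
    mean_se, se_ratio, divergence_rate), computed over converged
    iterations only.  ``spatial`` (when the scenario has a spatial term)
    holds the per-method mean RMSE of the recovered field.
    """

    per_iteration: pd.DataFrame
    summary: pd.DataFrame
    config: ScenarioConfig
    spatial: pd.DataFrame | None = None

    def to_csv(self, summary_path, per_iteration_path=None) -> None:
        self.summary.to_csv(summary_path, index=False)
        if per_iteration_path is not None:
            self.per_iteration.to_csv(per_iteration_path, index=False)


def _fit_one(dataset, method: str, model: str, design, c: float):
    if model == "fixed":
        if method == "poisson":
            return glm.fit_irls_poisson(dataset, overdispersed=False)
        if method == "odpoisson":
            return glm.fit_irls_poisson(dataset, overdispersed=True)
        if method == "negbin":
            return glm.fit_negbin(dataset)
        if method in ("loglinear", "taylor"):
            return glm.fit_comparator(dataset, method=method, c=c)
        if method == "proposed":
            return glm.fit_proposed(dataset)
        raise InvalidInputError(f"unknown fixed-effects method {method!r}")
    if method == "proposed":
        return mem.fit_mem_proposed(dataset, design)
    if method in ("poisson", "odpoisson", "taylor"):
        return mem.fit_mem_comparators(dataset, design, method=method, c=c)
    raise InvalidInputError(f"unknown mixed-model method {method!r}")


def _make_design(dataset, config: ScenarioConfig, model: str):
    blocks = []
    if model == "spatial":
        sp = config.spatial
        blocks.append(mem.build_lowrank_gp_basis(
            dataset.coords, rank=sp.rank, range_h=sp.range_h))
    elif model == "grouped":
        name, labels = dataset.groups[0]
        blocks.append(mem.build_group_design(labels, name=name))
    else:
        raise InvalidInputError(f"unknown model kind {model!r}")
    return mem.RandomEffectDesign(blocks)


def run_experiment(config: ScenarioConfig, methods=None, model: str = "fixed",
                   c: float = 0.5) -> ExperimentResult:
    """Run one Monte Carlo scenario and summarize estimator accuracy.

    Parameters
    ----------
    config
        Scenario description, including seed and replication count.
    methods
        Estimator names; defaults to all applicable to ``model``.
    model
        ``"fixed"``, ``"spatial"`` or ``"grouped"``; the latter two fit
        mixed models whose random design mirrors the generating process.
    c
        Tuning constant forwarded to the comparator transforms.

    Individual fit failures (divergence, non-convergence, singular
    designs) are caught and recorded as non-converged iterations; the
    experiment itself never aborts.
    """
    if methods is None:
        methods = FIXED_METHODS if model == "fixed" else MIXED_METHODS
    if model == "spatial" and config.spatial is None:
        raise InvalidInputError("model='spatial' needs config.spatial")
    if model == "grouped" and config.groups is None:
        raise InvalidInputError("model='grouped' needs config.groups")

    param_names = ["beta0"] + [f"beta{j + 1}" for j in
                               range(config.n_covariates)]
    rows = []
    spatial_rows = []
    for dataset, truth in build_scenario(config):
        it = truth["iteration"]
        design = None if model == "fixed" else _make_design(dataset, config, model)
        for method in methods:
            try:
                fit = _fit_one(dataset, method, model, design, c)
            except (LgpoisError, np.linalg.LinAlgError) as exc:
                rows.append((it, method, "beta0", np.nan, np.nan, False,
                             type(exc).__name__))
                continue
            se = fit.se
            for j, name in enumerate(param_names):
                rows.append((it, method, name, float(fit.beta[j]),
                             float(se[j]), True, ""))
            if model == "spatial":
                s_hat = fit.random_effect_predictions["spatial"]
                s_rmse = float(np.sqrt(np.mean((s_hat - truth["s"]) ** 2)))
                spatial_rows.append((it, method, s_rmse))
            rows.append((it, method, "sigma2", float(fit.sigma2), np.nan,
                         True, ""))

    per_iteration = pd.DataFrame(
        rows, columns=["iteration", "method", "parameter", "estimate", "se",
                       "converged", "error"])

    truth_map = {"sigma2": float(config.sigma2), "beta0": config.beta0}
    for j, b in enumerate(config.beta):
        truth_map[f"beta{j + 1}"] = b

    summary_rows = []
    for method in methods:
        sub = per_iteration[per_iteration["method"] == method]
        n_total = sub["iteration"].nunique()
        n_fail = sub.loc[~sub["converged"], "iteration"].nunique()
        div_rate = n_fail / n_total if n_total else np.nan
        ok = sub[sub["converged"]]
        for name in param_names + ["sigma2"]:
            vals = ok.loc[ok["parameter"] == name, "estimate"].to_numpy()
            ses = ok.loc[ok["parameter"] == name, "se"].to_numpy()
            if vals.size == 0:
                summary_rows.append((method, name, np.nan, np.nan, np.nan,
                                     np.nan, div_rate))
                continue
            rmse, bias = rmse_bias(vals, truth_map[name])
            mean_se = float(np.nanmean(ses)) if np.any(np.isfinite(ses)) else np.nan
            try:
                ratio = se_ratio(ses, vals) if np.any(np.isfinite(ses)) else np.nan
            except InvalidInputError:
                ratio = np.nan
            summary_rows.append((method, name, rmse, bias, mean_se, ratio,
                                 div_rate))
    summary = pd.DataFrame(
        summary_rows, columns=["method", "parameter", "rmse", "bias",
                               "mean_se", "se_ratio", "divergence_rate"])

    spatial = None
    if model == "spatial":
        sp = pd.DataFrame(spatial_rows, columns=["iteration", "method", "s_rmse"])
        spatial = (sp.groupby("method", as_index=False)["s_rmse"].mean()
                   .rename(columns={"s_rmse": "mean_s_rmse"}))
    return ExperimentResult(per_iteration=per_iteration, summary=summary,
                            config=config, spatial=spatial)
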