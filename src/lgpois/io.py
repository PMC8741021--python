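"""Dataset I/O, model specification, fit reports and benchmark grids.

This is the glue layer for working from files: a :class:`ModelSpec`
names the columns of a CSV (response, optional offset, covariates,
group labels, spatial coordinates) and the estimator to use;
:func:`read_dataset` validates and assembles a
:class:`~lgpois.data.CountDataset`; :func:`fit_model` dispatches to the
right estimator and returns a JSON-serializable report;
:func:`run_benchmark` sweeps a (beta0, sigma2, N) grid of Monte Carlo
scenarios and writes summary CSVs.  Specs and grid configurations can
be loaded from YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, mem
from .data import CountDataset
from .evaluate import run_experiment
from .exceptions import InvalidInputError, ValidationError
from .simulate import GroupConfig, ScenarioConfig, SpatialConfig
from .transforms import zero_ratio

__all__ = ["ModelSpec", "read_dataset", "write_dataset", "fit_model",
           "save_report", "run_benchmark"]

logger = logging.getLogger("lgpois")

METHODS = ("poisson", "odpoisson", "negbin", "loglinear", "taylor", "proposed")


@dataclass
class ModelSpec:
    """Which columns to use and which estimator to fit.

    ``spatial_term`` is ``(x_column, y_column)`` with optional ``rank``
    and ``range_h`` in ``options``.  ``options`` also carries the
    comparator constant ``c``, IRLS ``max_iter``/``tol`` and the
    REML/ML switch ``variance_method``.
    """

    response: str
    offset: str | None = None
    fixed_terms: list = field(default_factory=list)
    group_terms: list = field(default_factory=list)
    spatial_term: tuple | None = None
    method: str = "proposed"
    intercept: bool = True
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidInputError(
                f"unknown method {self.method!r}; expected one of {METHODS}")

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "spatial_term" in raw and raw["spatial_term"] is not None:
            raw["spatial_term"] = tuple(raw["spatial_term"])
        return cls(**raw)

    def used_columns(self) -> list[str]:
        cols = [self.response]
        if self.offset:
            cols.append(self.offset)
        cols += list(self.fixed_terms) + list(self.group_terms)
        if self.spatial_term:
            cols += list(self.spatial_term)
        return cols

    @property
    def is_mixed(self) -> bool:
        return bool(self.group_terms) or self.spatial_term is not None

    def resolved_options(self) -> dict:
        out = {"c": 0.5, "max_iter": 100, "tol": 1e-8,
               "variance_method": "reml", "rank": None, "range_h": None}
        out.update(self.options)
        return out


def read_dataset(path_or_frame, spec: ModelSpec) -> CountDataset:
    """Load and validate a CSV (or DataFrame) against a model spec.

    Rows with missing values in any used column are dropped (logged);
    negative or non-integer counts and non-positive offsets raise
    :class:`ValidationError` naming the offending rows.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    missing = [c for c in spec.used_columns() if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    used = spec.used_columns()
    n_before = len(df)
    df = df.dropna(subset=used)
    if len(df) < n_before:
        logger.info("dropped %d row(s) with missing values", n_before - len(df))
    if len(df) == 0:
        raise ValidationError("no complete rows remain after dropping missing values")

    y = pd.to_numeric(df[spec.response], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(y) | (y < 0) | (y != np.round(y)))
    if bad.size:
        raise ValidationError(
            f"column {spec.response!r}: non-negative integer counts required "
            f"(first bad row index: {df.index[bad[0]]})")
    if spec.offset:
        z = pd.to_numeric(df[spec.offset], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(z) | (z <= 0))
        if bad.size:
            raise ValidationError(
                f"column {spec.offset!r}: offsets must be positive "
                f"(first bad row index: {df.index[bad[0]]})")
    else:
        z = np.ones(len(df))

    cols = [np.ones(len(df))] if spec.intercept else []
    for name in spec.fixed_terms:
        col = pd.to_numeric(df[name], errors="coerce").to_numpy()
        if np.any(~np.isfinite(col)):
            raise ValidationError(f"column {name!r} contains non-numeric values")
        cols.append(col)
    if not cols:
        raise ValidationError("model has neither intercept nor covariates")
    X = np.column_stack(cols)

    groups = [(name, df[name].to_numpy()) for name in spec.group_terms]
    coords = None
    if spec.spatial_term:
        cx, cy = spec.spatial_term
        coords = df[[cx, cy]].to_numpy(dtype=float)
    return CountDataset(y=y, X=X, z=z, groups=groups, coords=coords)


def write_dataset(dataset: CountDataset, path, covariate_names=None) -> None:
    """Write a dataset to CSV (columns y, z, x1..xK, group*, coord_x/y)."""
    k = dataset.k
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(1, k + 1)]
    out = {"y": dataset.y.astype(int), "z": dataset.z}
    for j, name in enumerate(covariate_names):
        out[name] = dataset.X[:, j]
    for name, labels in dataset.groups:
        out[name] = labels
    if dataset.coords is not None:
        out["coord_x"] = dataset.coords[:, 0]
        out["coord_y"] = dataset.coords[:, 1]
    pd.DataFrame(out).to_csv(path, index=False)


def _build_design(dataset: CountDataset, spec: ModelSpec) -> mem.RandomEffectDesign:
    opts = spec.resolved_options()
    blocks = [mem.build_group_design(labels, name=name)
              for name, labels in dataset.groups]
    if dataset.coords is not None:
        blocks.append(mem.build_lowrank_gp_basis(
            dataset.coords, rank=opts["rank"], range_h=opts["range_h"]))
    return mem.RandomEffectDesign(blocks)


def fit_model(dataset: CountDataset, spec: ModelSpec) -> dict:
    """Fit the estimator named in ``spec`` and return a report dict.

    The report carries named coefficients with SEs and t-values, the
    dispersion estimate, the zero ratio r, convergence info, the
    resolved options, and (for mixed models) variance components and
    effective degrees of freedom.
    """
    opts = spec.resolved_options()
    r = zero_ratio(dataset.y)
    names = (["(intercept)"] if spec.intercept else []) + list(spec.fixed_terms)
    if spec.is_mixed:
        design = _build_design(dataset, spec)
        if spec.method == "proposed":
            fit = mem.fit_mem_proposed(dataset, design,
                                       method=opts["variance_method"])
        elif spec.method in ("poisson", "odpoisson", "taylor"):
            fit = mem.fit_mem_comparators(dataset, design, method=spec.method,
                                          c=opts["c"],
                                          reml=opts["variance_method"])
        else:
            raise InvalidInputError(
                f"method {spec.method!r} has no mixed-model form")
    else:
        if spec.method == "poisson":
            fit = glm.fit_irls_poisson(dataset, overdispersed=False,
                                       max_iter=opts["max_iter"],
                                       tol=opts["tol"])
        elif spec.method == "odpoisson":
            fit = glm.fit_irls_poisson(dataset, overdispersed=True,
                                       max_iter=opts["max_iter"],
                                       tol=opts["tol"])
        elif spec.method == "negbin":
            fit = glm.fit_negbin(dataset)
        elif spec.method in ("loglinear", "taylor"):
            fit = glm.fit_comparator(dataset, method=spec.method, c=opts["c"])
        else:
            fit = glm.fit_proposed(dataset)

    se = fit.se
    coef = []
    for j, name in enumerate(names):
        coef.append({"name": name, "estimate": float(fit.beta[j]),
                     "se": float(se[j]),
                     "t_value": float(fit.beta[j] / se[j]) if se[j] > 0 else None})
    report = {
        "method": spec.method,
        "n": dataset.n,
        "zero_ratio": r,
        "coefficients": coef,
        "sigma2": float(fit.sigma2),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "options": opts,
        "fitted_lambda": [float(v) for v in fit.lambda_hat],
    }
    if hasattr(fit, "edof"):
        report["edof"] = float(fit.edof)
        report["tau2"] = [float(t) for t in fit.tau2]
    logger.info("fit %s: r=%.3f, sigma2=%.3f, converged=%s",
                spec.method, r, fit.sigma2, fit.converged)
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def run_benchmark(grid: dict, out_dir, seed: int | None = None,
                  reps: int | None = None) -> pd.DataFrame:
    """Sweep a Monte Carlo grid and write one summary CSV per cell.

    ``grid`` mirrors the YAML layout::

        beta0: [-2, -1, 0, 1, 2]
        sigma2: [1, 5]
        n: [50, 200]
        beta: [2.0, 0.5]
        methods: [poisson, proposed]
        model: fixed          # or spatial / grouped
        n_iter: 200
        seed: 1
        spatial: {scale: 1.0}   # when model: spatial
        groups: {n_groups: 10, effect_sd: 1.0}

    ``seed`` and ``reps`` override the config.  Returns the concatenated
    summary with the grid coordinates attached; also writes ``index.json``
    recording the fully resolved configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = dict(grid)
    if seed is not None:
        grid["seed"] = seed
    if reps is not None:
        grid["n_iter"] = reps
    model = grid.get("model", "fixed")
    methods = grid.get("methods")
    beta = tuple(grid.get("beta", (2.0, 0.5)))
    base_seed = int(grid.get("seed", 0))
    n_iter = int(grid.get("n_iter", 200))
    spatial = SpatialConfig(**grid["spatial"]) if "spatial" in grid else None
    groups = GroupConfig(**grid["groups"]) if "groups" in grid else None

    frames, index = [], []
    cell = 0
    for n in grid.get("n", [200]):
        for sigma2 in grid.get("sigma2", [1.0]):
            for beta0 in grid.get("beta0", [0.0]):
                config = ScenarioConfig(
                    n=int(n), beta0=float(beta0), beta=beta,
                    sigma2=float(sigma2), spatial=spatial, groups=groups,
                    seed=base_seed + 1000 * cell, n_iter=n_iter)
                result = run_experiment(config, methods=methods, model=model)
                name = f"summary_n{n}_s{sigma2}_b{beta0}.csv"
                result.to_csv(out_dir / name)
                summary = result.summary.copy()
                summary.insert(0, "beta0", float(beta0))
                summary.insert(0, "sigma2", float(sigma2))
                summary.insert(0, "n", int(n))
                frames.append(summary)
                index.append({"file": name, "n": int(n), "sigma2": float(sigma2),
                              "beta0": float(beta0),
                              "seed": config.seed, "n_iter": n_iter})
                cell += 1
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out_dir / "summary_all.csv", index=False)
    with open(out_dir / "index.json", "w") as fh:
        json.dump({"model": model, "methods": list(methods) if methods else None,
                   "beta": list(beta), "seed": base_seed, "n_iter": n_iter,
                   "cells": index}, fh, indent=2)
    return combined
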