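"""Synthetic screening-cohort generator.

Generates cohorts with the statistical structure the analysis assumes:
covariate marginals matching a large unselected first-trimester screening
population, biomarkers drawn from the competing-risks model's own likelihood
(so the biomarker-outcome dependence is exactly the one the scorer inverts),
a blood-pressure pair reconciled with the generated MAP marker, and a
competing other-cause delivery time.

Per pregnancy, in order: covariates -> prior mean mu -> latent pre-eclampsia
delivery age g_pe ~ Normal(mu, sigma) truncated to [g_min, inf) -> log10 MoMs
~ MVN(m(g_pe), Sigma) -> raw markers = MoM x expected median -> systolic
pressure from MAP (sbp = a + b MAP + noise) with dbp = (3 MAP - sbp)/2, so
that (sbp + 2 dbp)/3 reproduces the generated MAP exactly -> other-cause
delivery age g_other (truncated normal, drawn conditional on g_other >= g_pe
when g_pe <= g_max) -> outcome by the competition rule
pe = (g_pe <= g_other and g_pe <= g_max), delivery at min(g_pe, g_other).

Drawing g_other above g_pe for pre-eclampsia-bound rows realises the
scoring model's own assumption that no other delivery pre-empts
pre-eclampsia inside the risk window; see docs/methods.md for what this
deliberately does not emulate about real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import MARKERS, CATEGORICAL_LEVELS
from .params import ConfigError, RiskModelParams, load_config, params_from_dict
from .risk_model import expected_log10_marker, prior_ga_mean

__all__ = ["GeneratorConfig", "default_generator_config", "simulate_cohort",
           "covariate_marginal_report"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to simulate a cohort (see data/default_params.yaml)."""

    n: int
    seed: int
    covariates: dict
    bp_model: dict               # sbp_intercept, sbp_slope, sbp_noise_sd
    other_cause: dict            # mean, sd, min, max
    risk_model: RiskModelParams = field(repr=False, default=None)

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for cat in CATEGORICAL_LEVELS:
            probs = self.covariates.get(cat)
            if probs is None:
                continue
            bad = set(probs) - set(CATEGORICAL_LEVELS[cat])
            if bad:
                raise ConfigError(f"unknown {cat} levels: {sorted(bad)}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{cat} proportions must sum to 1")
        if self.other_cause["sd"] <= 0 or self.bp_model["sbp_noise_sd"] < 0:
            raise ConfigError("scale parameters must be positive")
        if self.risk_model is None:
            raise ConfigError("generator needs a risk_model parameter set")


def generator_from_dict(cfg: dict, params: RiskModelParams) -> GeneratorConfig:
    g = cfg["generator"]
    return GeneratorConfig(
        n=int(g.get("n", 50000)), seed=int(g.get("seed", 0)),
        covariates=dict(g["covariates"]), bp_model=dict(g["bp_model"]),
        other_cause=dict(g["other_cause"]), risk_model=params,
    )


def default_generator_config(path=None, n=None, seed=None) -> GeneratorConfig:
    cfg = load_config(path)
    gc = generator_from_dict(cfg, params_from_dict(cfg["risk_model"]))
    if n is not None or seed is not None:
        gc = GeneratorConfig(n=n if n is not None else gc.n,
                             seed=seed if seed is not None else gc.seed,
                             covariates=gc.covariates, bp_model=gc.bp_model,
                             other_cause=gc.other_cause, risk_model=gc.risk_model)
    return gc


def _categorical(rng, levels, probs_map, n):
    levels = list(levels)
    p = np.array([probs_map.get(lv, 0.0) for lv in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _truncnorm(rng, mean, sd, lo, hi, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_covariates(rng, cov: dict, n: int) -> pd.DataFrame:
    d = {}
    a = cov["age"]
    d["age"] = _truncnorm(rng, a["mean"], a["sd"], a["min"], a["max"], n)
    # height and log-BMI via a Gaussian copula so weight-height correlate
    rho = float(cov.get("weight_height_corr", 0.4))
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    h = cov["height"]
    d["height"] = np.clip(h["mean"] + h["sd"] * z[:, 0], 121.0, 209.0)
    b = cov["bmi"]
    bmi = np.exp(np.log(b["median"]) + b["sigma_log"] * z[:, 1])
    d["weight"] = np.clip(bmi * (d["height"] / 100.0) ** 2, 31.0, 249.0)
    d["ethnic_group"] = _categorical(rng, CATEGORICAL_LEVELS["ethnic_group"],
                                     cov["ethnic_group"], n)
    d["smoker"] = (rng.random(n) < cov["smoker"]).astype(int)
    d["family_history_pe"] = (rng.random(n) < cov["family_history_pe"]).astype(int)
    d["conception"] = np.where(rng.random(n) < cov["conception_assisted"],
                               "assisted", "spontaneous")
    d["parity"] = _categorical(rng, CATEGORICAL_LEVELS["parity"], cov["parity"], n)
    ipi_cfg = cov["interpregnancy_interval"]
    ipi = np.exp(np.log(ipi_cfg["median"]) + ipi_cfg["sigma_log"] * rng.standard_normal(n))
    ipi = np.clip(ipi, 0.4, 20.0)
    d["interpregnancy_interval"] = np.where(d["parity"] == "nulliparous", np.nan, ipi)
    d["chronic_hypertension"] = (rng.random(n) < cov["chronic_hypertension"]).astype(int)
    d["diabetes"] = _categorical(rng, CATEGORICAL_LEVELS["diabetes"], cov["diabetes"], n)
    d["sle_aps"] = (rng.random(n) < cov["sle_aps"]).astype(int)
    g = cov["ga_screening"]
    d["ga_screening"] = _truncnorm(rng, g["mean"], g["sd"], g["min"], g["max"], n)
    return pd.DataFrame(d)


def simulate_cohort(config: GeneratorConfig, n: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort table; reproducible given (config, seed)."""
    n = config.n if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    if n < 1:
        raise ConfigError("n must be >= 1")
    params = config.risk_model
    rng = np.random.default_rng(seed)

    df = _draw_covariates(rng, config.covariates, n)
    mu = np.asarray(prior_ga_mean(df, params), dtype=float)

    # latent age at delivery with pre-eclampsia, conditioned on >= g_min
    a = (params.grid_min - mu) / params.prior_sd
    g_pe = truncnorm.rvs(a, np.inf, loc=mu, scale=params.prior_sd,
                         size=n, random_state=rng)

    # biomarker log10 MoMs around the changepoint mean profile
    mean = np.column_stack([params.markers[m].mean_log10_mom(g_pe) for m in MARKERS])
    L = np.linalg.cholesky(params.residual_cov)
    moms = mean + rng.standard_normal((n, 3)) @ L.T

    raw = {}
    for j, name in enumerate(MARKERS):
        raw[name] = 10.0 ** (expected_log10_marker(name, df, params) + moms[:, j])
    map_val = raw["map"]
    df["uta_pi"] = raw["uta_pi"]
    df["plgf"] = raw["plgf"]

    # blood pressure reconciled with the generated MAP marker
    bp = config.bp_model
    sbp = bp["sbp_intercept"] + bp["sbp_slope"] * map_val \
        + bp["sbp_noise_sd"] * rng.standard_normal(n)
    dbp = (3.0 * map_val - sbp) / 2.0
    low = dbp < 50.5          # keep the cohort invariant 50 <= dbp < sbp
    dbp = np.where(low, 50.5, dbp)
    sbp = np.where(low, 3.0 * map_val - 2.0 * dbp, sbp)
    sbp = np.minimum(sbp, 259.0)
    df["sbp"] = sbp
    df["dbp"] = dbp

    # other-cause delivery; for pre-eclampsia-bound rows the (never observed)
    # counterfactual other-cause time lies above g_pe by construction
    oc = config.other_cause
    lo = np.full(n, oc["min"], dtype=float)
    case = g_pe <= params.grid_max
    lo[case] = np.maximum(lo[case], g_pe[case])
    near_top = lo > oc["max"] - 1e-9
    lo = np.minimum(lo, oc["max"] - 1e-9)
    a_oc = (lo - oc["mean"]) / oc["sd"]
    b_oc = (oc["max"] - oc["mean"]) / oc["sd"]
    g_other = truncnorm.rvs(a_oc, b_oc, loc=oc["mean"], scale=oc["sd"],
                            size=n, random_state=rng)
    g_other[near_top] = oc["max"]

    pe = case & (g_pe <= g_other)
    df["g_pe"] = g_pe
    df["g_other"] = g_other
    df["pe"] = pe.astype(int)
    df["ga_delivery"] = np.minimum(np.minimum(g_pe, g_other), params.grid_max)
    return df


def covariate_marginal_report(cohort: pd.DataFrame,
                              config: GeneratorConfig) -> pd.DataFrame:
    """Observed vs configured marginals: proportions per categorical level,
    median and IQR per continuous field."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    cov = config.covariates
    for cat, levels in CATEGORICAL_LEVELS.items():
        target = cov.get(cat, {})
        for lv in levels:
            rows.append({"field": cat, "level": lv,
                         "observed": float((cohort[cat] == lv).mean()),
                         "target": float(target.get(lv, np.nan))})
    for flagcol, key in (("smoker", "smoker"),
                         ("family_history_pe", "family_history_pe"),
                         ("chronic_hypertension", "chronic_hypertension"),
                         ("sle_aps", "sle_aps")):
        rows.append({"field": flagcol, "level": "true",
                     "observed": float(cohort[flagcol].mean()),
                     "target": float(cov[key])})
    rows.append({"field": "conception", "level": "assisted",
                 "observed": float((cohort["conception"] == "assisted").mean()),
                 "target": float(cov["conception_assisted"])})
    for col in ("age", "weight", "height", "ga_screening", "dbp", "sbp",
                "ga_delivery"):
        if col not in cohort.columns:
            continue
        q = cohort[col].quantile([0.25, 0.5, 0.75])
        rows.append({"field": col, "level": "median (IQR)",
                     "observed": float(q.loc[0.5]),
                     "observed_iqr": (float(q.loc[0.25]), float(q.loc[0.75])),
                     "target": np.nan})
    return pd.DataFrame(rows)
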