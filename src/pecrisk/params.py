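"""Model parameters and their configuration file.

All coefficients of the competing-risks model live in a structured YAML file
(a versioned default ships with the package as ``data/default_params.yaml``).
The defaults are *synthetic*: they are documented values chosen so that the
bundled cohort generator reproduces incidences and blood-pressure strata on
the scale reported for large first-trimester screening populations, not a fit
to any proprietary dataset.

Effect terms
------------
Covariate effects (for the prior gestational-age mean, in weeks, and for the
marker median regressions, in log10 units) are declared per covariate:

* ``covariate: <number>`` — shift applied when a boolean flag is set;
* ``covariate: {per_unit: a, center: c}`` — linear term ``a * (x - c)``
  (missing values contribute zero, e.g. the interpregnancy interval of a
  nulliparous woman);
* ``covariate: {per_unit: a, hinge: h}`` — one-sided term ``a * max(x-h, 0)``;
* ``covariate: {level: shift, ...}`` — categorical offsets from the reference
  level (levels not listed shift by zero).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CATEGORICAL_LEVELS, FLAG_COLUMNS, MARKERS, UnknownLevelError

_TERM_KEYS = {"per_unit", "center", "hinge"}


class ConfigError(ValueError):
    """Invalid or inconsistent model configuration."""


def _validate_effects(effects: Mapping, where: str) -> None:
    for cov, spec in effects.items():
        if cov in FLAG_COLUMNS:
            if not isinstance(spec, (int, float)):
                raise ConfigError(f"{where}: flag covariate {cov!r} needs a numeric shift")
        elif cov in CATEGORICAL_LEVELS:
            if not isinstance(spec, Mapping):
                raise ConfigError(f"{where}: categorical covariate {cov!r} needs a level map")
            bad = set(spec) - set(CATEGORICAL_LEVELS[cov])
            if bad:
                raise ConfigError(f"{where}: unknown {cov} levels in config: {sorted(bad)}")
        elif isinstance(spec, Mapping):
            if not spec.keys() <= _TERM_KEYS or "per_unit" not in spec:
                raise ConfigError(f"{where}: malformed term for {cov!r}: {dict(spec)}")
        else:
            raise ConfigError(f"{where}: continuous covariate {cov!r} needs "
                              "{per_unit, center|hinge}")


def evaluate_effects(df: pd.DataFrame, effects: Mapping) -> np.ndarray:
    """Sum of additive covariate effects, one value per row of ``df``."""
    out = np.zeros(len(df), dtype=float)
    for cov, spec in effects.items():
        if cov not in df.columns:
            raise ConfigError(f"covariate {cov!r} not in cohort columns")
        col = df[cov]
        if cov in CATEGORICAL_LEVELS:
            bad = set(col.unique()) - set(CATEGORICAL_LEVELS[cov])
            if bad:
                raise UnknownLevelError(cov, sorted(bad)[0])
            out += col.map(lambda lv: float(spec.get(lv, 0.0))).to_numpy(float)
        elif isinstance(spec, Mapping):
            x = pd.to_numeric(col, errors="coerce").to_numpy(float)
            if "hinge" in spec:
                term = float(spec["per_unit"]) * np.maximum(x - float(spec["hinge"]), 0.0)
            else:
                term = float(spec["per_unit"]) * (x - float(spec.get("center", 0.0)))
            out += np.where(np.isnan(term), 0.0, term)
        else:
            out += float(spec) * col.to_numpy(float)
    return out


@dataclass(frozen=True)
class MarkerModel:
    """One biomarker's MoM regression and its likelihood mean profile.

    The mean log10 MoM for a pregnancy destined to deliver with pre-eclampsia
    at gestation ``g`` is ``slope * (g - changepoint)`` for ``g`` below the
    changepoint and zero at or beyond it.
    """

    name: str
    intercept_log10: float
    regression: dict = field(default_factory=dict)
    slope: float = 0.0          # log10 MoM per week, g < changepoint
    changepoint: float = 40.0   # weeks

    def mean_log10_mom(self, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return self.slope * (np.minimum(g, self.changepoint) - self.changepoint)


@dataclass(frozen=True)
class RiskModelParams:
    """All coefficients of the competing-risks pre-eclampsia model."""

    prior_intercept: float               # mu0, weeks
    prior_sd: float                      # sigma, weeks
    prior_effects: dict
    markers: dict                        # name -> MarkerModel, keys == MARKERS
    residual_cov: np.ndarray             # 3x3, log10 MoM, order == MARKERS
    grid_min: float = 24.0
    grid_max: float = 42.0
    grid_step: float = 0.025
    band_cuts: tuple = (32.0, 34.0, 37.0)

    def __post_init__(self):
        if self.prior_sd <= 0:
            raise ConfigError("prior_sd must be positive")
        if self.grid_step <= 0 or self.grid_min >= self.grid_max:
            raise ConfigError("grid must satisfy min < max and step > 0")
        for c in self.band_cuts:
            if not self.grid_min < c < self.grid_max:
                raise ConfigError(f"band cut {c} outside grid ({self.grid_min}, {self.grid_max})")
        cov = np.asarray(self.residual_cov, dtype=float)
        if cov.shape != (len(MARKERS), len(MARKERS)):
            raise ConfigError("residual_cov must be 3x3 in marker order map, uta_pi, plgf")
        if not np.allclose(cov, cov.T):
            raise ConfigError("residual_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ConfigError("residual_cov must be positive definite")
        object.__setattr__(self, "residual_cov", cov)
        if set(self.markers) != set(MARKERS):
            raise ConfigError(f"markers must be exactly {MARKERS}")
        _validate_effects(self.prior_effects, "prior.effects")
        for name, m in self.markers.items():
            _validate_effects(m.regression, f"markers.{name}.regression")

    def marker_index(self, name: str) -> int:
        return MARKERS.index(name)

    def sub_cov(self, names) -> np.ndarray:
        idx = [self.marker_index(n) for n in names]
        return self.residual_cov[np.ix_(idx, idx)]


def _marker_from_dict(name: str, d: Mapping) -> MarkerModel:
    try:
        return MarkerModel(
            name=name,
            intercept_log10=float(d["intercept_log10"]),
            regression=dict(d.get("regression", {})),
            slope=float(d["slope"]),
            changepoint=float(d["changepoint"]),
        )
    except KeyError as e:
        raise ConfigError(f"markers.{name}: missing key {e}") from e


def params_from_dict(cfg: Mapping) -> RiskModelParams:
    try:
        prior = cfg["prior"]
        markers_cfg = cfg["markers"]
        resid = cfg["residual"]
        grid = cfg.get("grid", {})
    except KeyError as e:
        raise ConfigError(f"config missing section {e}") from e
    if isinstance(resid.get("cov"), list):
        cov = np.asarray(resid["cov"], dtype=float)
    else:
        sd = np.array([float(resid["sd"][m]) for m in MARKERS])
        corr = np.eye(3)
        pairs = {("map", "uta_pi"): 0, ("map", "plgf"): 1, ("uta_pi", "plgf"): 2}
        for (a, b), _ in pairs.items():
            r = float(resid.get("corr", {}).get(f"{a}__{b}", 0.0))
            i, j = MARKERS.index(a), MARKERS.index(b)
            corr[i, j] = corr[j, i] = r
        cov = corr * np.outer(sd, sd)
    markers = {m: _marker_from_dict(m, markers_cfg[m]) for m in MARKERS}
    return RiskModelParams(
        prior_intercept=float(prior["intercept"]),
        prior_sd=float(prior["sd"]),
        prior_effects=dict(prior.get("effects", {})),
        markers=markers,
        residual_cov=cov,
        grid_min=float(grid.get("min", 24.0)),
        grid_max=float(grid.get("max", 42.0)),
        grid_step=float(grid.get("step", 0.025)),
        band_cuts=tuple(float(c) for c in grid.get("band_cuts", (32.0, 34.0, 37.0))),
    )


def load_config(path=None) -> dict:
    """Load the full YAML configuration (risk model + generator sections)."""
    if path is None:
        ref = importlib.resources.files("pecrisk").joinpath("data/default_params.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "risk_model" not in cfg:
        raise ConfigError("configuration must contain a 'risk_model' section")
    return cfg


def load_params(path=None) -> RiskModelParams:
    return params_from_dict(load_config(path)["risk_model"])


def default_params() -> RiskModelParams:
    return load_params(None)
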