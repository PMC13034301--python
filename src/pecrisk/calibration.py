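"""Calibration diagnostics for predicted pre-eclampsia risks.

Agreement between predicted risks and observed binary outcomes is quantified
by a binned calibration table and by two logistic-regression summaries on the
logit scale:

* calibration-in-the-large (intercept): the intercept alpha of a logistic
  regression of outcomes on logit(risk) with the slope fixed at 1, i.e. an
  intercept-only Bernoulli fit with logit(risk) as a fixed offset.  0 for
  perfectly calibrated risks;
* calibration slope: the slope beta of the two-parameter logistic fit of
  outcomes on logit(risk).  1 for perfectly calibrated risks.

Risks are clipped to [1e-8, 1 - 1e-8] before the logit transform; clipping is
logged.  Fits use iteratively reweighted least squares (statsmodels GLM,
Binomial family) to a 1e-8 tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

_CLIP = 1e-8


class SeparationError(ValueError):
    """All outcomes are events or all are non-events; no estimate exists."""


def _check_inputs(risks, outcomes):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape or r.ndim != 1:
        raise ValueError("risks and outcomes must be aligned 1-d arrays")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("outcomes must be binary")
    if np.any(~np.isfinite(r)) or np.any(r <= 0) or np.any(r >= 1):
        raise ValueError("risks must lie strictly in (0, 1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise SeparationError("outcomes are all events or all non-events")
    return r, y


def _logit(r):
    n_clip = int(np.sum((r < _CLIP) | (r > 1 - _CLIP)))
    if n_clip:
        log.info("clipping %d risks to [%g, %g] before logit", n_clip, _CLIP, 1 - _CLIP)
    r = np.clip(r, _CLIP, 1 - _CLIP)
    return np.log(r / (1 - r))


@dataclass(frozen=True)
class CalibrationResult:
    intercept: float                     # alpha, log-odds
    slope: float                         # beta
    bins: pd.DataFrame                   # mean_predicted, observed_incidence, n

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope,
                "bins": self.bins.to_dict(orient="records")}


def calibration_bins(risks, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count calibration bins sorted by predicted risk.

    Ties are broken by stable input order.  Returns a frame with columns
    ``mean_predicted``, ``observed_incidence``, ``n``.
    """
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if n_bins > len(r):
        raise ValueError(f"n_bins={n_bins} exceeds number of rows {len(r)}")
    order = np.argsort(r, kind="stable")
    edges = np.linspace(0, len(r), n_bins + 1).round().astype(int)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = order[lo:hi]
        rows.append({"mean_predicted": float(r[sel].mean()),
                     "observed_incidence": float(y[sel].mean()),
                     "n": int(hi - lo)})
    return pd.DataFrame(rows)


def calibration_intercept(risks, outcomes) -> float:
    """Calibration-in-the-large: intercept with the slope fixed at 1."""
    r, y = _check_inputs(risks, outcomes)
    offset = _logit(r)
    model = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                   offset=offset)
    fit = model.fit(tol=1e-10)
    return float(fit.params[0])


def calibration_slope(risks, outcomes) -> float:
    """Slope of the two-parameter logistic fit of outcomes on logit(risk)."""
    r, y = _check_inputs(risks, outcomes)
    lg = _logit(r)
    if np.ptp(lg) == 0:
        raise ValueError("risks have zero variance; slope is undefined")
    X = sm.add_constant(lg)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10)
    return float(fit.params[1])


def calibrate(risks, outcomes, n_bins: int = 10) -> CalibrationResult:
    """Full calibration summary: intercept, slope and bin table."""
    return CalibrationResult(
        intercept=calibration_intercept(risks, outcomes),
        slope=calibration_slope(risks, outcomes),
        bins=calibration_bins(risks, outcomes, n_bins=n_bins),
    )


def calibration_plot(result: CalibrationResult, path) -> None:
    """Observed-vs-predicted bin plot with the identity line (optional;
    requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    b = result.bins
    ax.plot([0, b["mean_predicted"].max() * 1.05], [0, b["mean_predicted"].max() * 1.05],
            ls="--", c="grey", lw=1, label="perfect calibration")
    ax.plot(b["mean_predicted"], b["observed_incidence"], "o-", c="tab:blue")
    ax.set_xlabel("mean predicted risk")
    ax.set_ylabel("observed incidence")
    ax.set_title(f"intercept {result.intercept:.3f}, slope {result.slope:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
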