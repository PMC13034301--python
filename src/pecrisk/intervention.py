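"""Counterfactual blood-pressure lowering.

A threshold/target policy offers antihypertensive treatment to every
pregnancy whose diastolic pressure strictly exceeds the threshold; the
modelled attained diastolic pressure equals the target, and systolic
pressure falls by a fixed ratio (default 5.8/4.6 mm Hg systolic per mm Hg
diastolic, the reduction ratio achieved in CHIPS) per mm Hg of diastolic
reduction.  Mean arterial pressure is recomputed from the capped pair and
the competing-risks model re-scored; the MoM denominator keeps the
pre-treatment covariate regression, so only the observed MAP changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import RiskModelParams
from .risk_model import score_cohort

log = logging.getLogger(__name__)

#: systolic mm Hg lowered per diastolic mm Hg (CHIPS: 5.8 / 4.6)
DEFAULT_SBP_RATIO = 5.8 / 4.6

#: minimum systolic-over-diastolic gap preserved by the simulated treatment
_SBP_GAP = 5.0


@dataclass(frozen=True)
class BloodPressure:
    sbp: float  # mm Hg
    dbp: float  # mm Hg

    def __post_init__(self):
        if not (50.0 <= self.dbp < self.sbp <= 260.0):
            raise ValueError(f"blood pressure outside 50 <= dbp < sbp <= 260: "
                             f"({self.sbp}, {self.dbp})")


@dataclass(frozen=True)
class InterventionPolicy:
    """Treat when dbp > threshold; modelled attained dbp equals target."""

    dbp_threshold: float
    dbp_target: float
    sbp_ratio: float = DEFAULT_SBP_RATIO
    name: str = ""

    def __post_init__(self):
        if self.dbp_target > self.dbp_threshold:
            raise ValueError("dbp_target must not exceed dbp_threshold")
        if self.sbp_ratio < 0:
            raise ValueError("sbp_ratio must be non-negative")


#: the four policies examined in the analysis
NAMED_POLICIES = {
    "current-care": InterventionPolicy(90.0, 85.0, name="current-care"),
    "t85": InterventionPolicy(85.0, 85.0, name="t85"),
    "t80": InterventionPolicy(80.0, 80.0, name="t80"),
    "t75": InterventionPolicy(75.0, 75.0, name="t75"),
}


def get_policy(name_or_policy) -> InterventionPolicy:
    if isinstance(name_or_policy, InterventionPolicy):
        return name_or_policy
    try:
        return NAMED_POLICIES[name_or_policy]
    except KeyError:
        raise KeyError(f"unknown policy {name_or_policy!r}; "
                       f"known: {sorted(NAMED_POLICIES)}") from None


def mean_arterial_pressure(bp) -> float:
    """MAP = (sbp + 2 dbp) / 3.  Accepts a BloodPressure or an (sbp, dbp)
    pair (the latter without invariant checks, e.g. for formula tests)."""
    sbp, dbp = (bp.sbp, bp.dbp) if isinstance(bp, BloodPressure) else bp
    return (sbp + 2.0 * dbp) / 3.0


def apply_policy(bp: BloodPressure, policy: InterventionPolicy):
    """Cap the diastolic pressure at the policy target.

    Returns ``(BloodPressure, treated)``.  Untreated pressures pass through
    unchanged; treated systolic pressure falls by ``sbp_ratio`` per mm Hg of
    diastolic reduction, floored to stay above ``dbp + 5`` mm Hg but never
    raised above its pre-treatment value.  Idempotent: the attained dbp does
    not exceed the threshold.
    """
    if bp.dbp <= policy.dbp_threshold:
        return bp, False
    drop = bp.dbp - policy.dbp_target
    sbp_new = bp.sbp - policy.sbp_ratio * drop
    floor = policy.dbp_target + _SBP_GAP
    if sbp_new < floor:
        sbp_new = floor
        if sbp_new > bp.sbp:
            log.warning("systolic floor %.1f exceeds pre-treatment sbp %.1f; "
                        "keeping sbp unchanged", floor, bp.sbp)
            sbp_new = bp.sbp
        else:
            log.warning("systolic reduction floored at dbp_target + %.0f mm Hg", _SBP_GAP)
    return BloodPressure(sbp_new, policy.dbp_target), True


def apply_policy_cohort(df: pd.DataFrame, policy: InterventionPolicy):
    """Vectorised :func:`apply_policy` over the cohort's sbp/dbp columns.

    Returns ``(sbp_new, dbp_new, treated)`` arrays.
    """
    sbp = pd.to_numeric(df["sbp"], errors="coerce").to_numpy(float)
    dbp = pd.to_numeric(df["dbp"], errors="coerce").to_numpy(float)
    treated = dbp > policy.dbp_threshold
    dbp_new = np.where(treated, policy.dbp_target, dbp)
    sbp_cf = sbp - policy.sbp_ratio * (dbp - policy.dbp_target)
    floor = policy.dbp_target + _SBP_GAP
    sbp_cf = np.minimum(np.maximum(sbp_cf, floor), sbp)
    n_floor = int(np.sum(treated & (sbp - policy.sbp_ratio * (dbp - policy.dbp_target) < floor)))
    if n_floor:
        log.warning("systolic floor bound on %d treated rows", n_floor)
    sbp_new = np.where(treated, sbp_cf, sbp)
    return sbp_new, dbp_new, treated


def rescore_cohort(df: pd.DataFrame, policy, params: RiskModelParams):
    """Baseline and counterfactual band risks for every pregnancy.

    Returns ``(baseline, counterfactual, treated)`` where the first two are
    frames from :func:`pecrisk.risk_model.score_cohort` and ``treated`` is a
    boolean array.  Untreated rows keep their baseline risks exactly; for
    treated rows the MAP MoM is recomputed from the capped blood pressure
    (the expected MAP is unchanged: denominators use pre-treatment
    covariates) and the posterior re-evaluated.
    """
    policy = get_policy(policy)
    baseline = score_cohort(df, params)
    sbp_new, dbp_new, treated = apply_policy_cohort(df, policy)
    counterfactual = baseline.copy()
    if treated.any():
        sub = df.loc[treated]
        map_new = (sbp_new[treated] + 2.0 * dbp_new[treated]) / 3.0
        counterfactual.loc[treated] = score_cohort(sub, params, map_values=map_new)
    return baseline, counterfactual, treated
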