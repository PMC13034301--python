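"""Domain types and the cohort-table schema.

A cohort is a :class:`pandas.DataFrame` with one row per singleton pregnancy
screened at 11-13 weeks. :class:`MaternalProfile` is the single-pregnancy view
used by the per-woman risk API; the vectorised pipeline operates on the frame
directly.  Units: age years, weight kg, height cm, gestational ages in weeks
(decimal), blood pressures mm Hg, PlGF pg/mL, UtA-PI dimensionless.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

ETHNIC_LEVELS = ("white", "black", "south_asian", "east_asian", "mixed")
CONCEPTION_LEVELS = ("spontaneous", "assisted")
PARITY_LEVELS = ("nulliparous", "parous_no_pe", "parous_prior_pe")
DIABETES_LEVELS = ("none", "type1", "type2")

CATEGORICAL_LEVELS = {
    "ethnic_group": ETHNIC_LEVELS,
    "conception": CONCEPTION_LEVELS,
    "parity": PARITY_LEVELS,
    "diabetes": DIABETES_LEVELS,
}
FLAG_COLUMNS = ("smoker", "family_history_pe", "chronic_hypertension", "sle_aps")
CONTINUOUS_COLUMNS = (
    "age", "weight", "height", "interpregnancy_interval", "ga_screening",
    "sbp", "dbp", "uta_pi", "plgf",
)

#: columns every cohort CSV must carry (outcome columns are optional)
REQUIRED_COLUMNS = (
    "age", "weight", "height", "ethnic_group", "smoker", "family_history_pe",
    "conception", "parity", "interpregnancy_interval", "chronic_hypertension",
    "diabetes", "sle_aps", "ga_screening", "sbp", "dbp", "uta_pi", "plgf",
)
OUTCOME_COLUMNS = ("pe", "ga_delivery")
LATENT_COLUMNS = ("g_pe", "g_other")

MARKERS = ("map", "uta_pi", "plgf")


class UnknownLevelError(ValueError):
    """A categorical covariate carries a level outside its declared set."""

    def __init__(self, column: str, level):
        self.column = column
        self.level = level
        super().__init__(f"unknown level {level!r} for covariate {column!r}; "
                         f"allowed: {CATEGORICAL_LEVELS[column]}")


@dataclass(frozen=True)
class MaternalProfile:
    """Maternal characteristics and history driving the prior and the MoM
    regressions."""

    age: float
    weight: float
    height: float
    ethnic_group: str = "white"
    smoker: bool = False
    family_history_pe: bool = False
    conception: str = "spontaneous"
    parity: str = "parous_no_pe"
    interpregnancy_interval: Optional[float] = None
    chronic_hypertension: bool = False
    diabetes: str = "none"
    sle_aps: bool = False
    ga_screening: float = 12.7

    def __post_init__(self):
        if not 12.0 <= self.age <= 60.0:
            raise ValueError(f"age {self.age} outside [12, 60]")
        if not 30.0 <= self.weight <= 250.0:
            raise ValueError(f"weight {self.weight} outside [30, 250]")
        if not 120.0 <= self.height <= 210.0:
            raise ValueError(f"height {self.height} outside [120, 210]")
        if not 11.0 <= self.ga_screening <= 14.2:
            raise ValueError(f"ga_screening {self.ga_screening} outside [11.0, 14.2]")
        for col in ("ethnic_group", "conception", "parity", "diabetes"):
            if getattr(self, col) not in CATEGORICAL_LEVELS[col]:
                raise UnknownLevelError(col, getattr(self, col))
        has_ipi = self.interpregnancy_interval is not None and not (
            isinstance(self.interpregnancy_interval, float)
            and math.isnan(self.interpregnancy_interval))
        if self.parity == "nulliparous" and has_ipi:
            raise ValueError("interpregnancy_interval must be absent for nulliparous")
        if self.parity != "nulliparous" and not has_ipi:
            raise ValueError("interpregnancy_interval required when parous")

    def reference(**overrides) -> "MaternalProfile":  # noqa: N805 - factory
        """Reference woman: white, parous without previous pre-eclampsia,
        no medical history, at the covariate centring points."""
        base = dict(age=31.0, weight=69.0, height=164.0,
                    interpregnancy_interval=2.9)
        base.update(overrides)
        return MaternalProfile(**base)

    reference = staticmethod(reference)

    def as_row(self) -> dict:
        d = dataclasses.asdict(self)
        for col in FLAG_COLUMNS:
            d[col] = int(d[col])
        if d["interpregnancy_interval"] is None:
            d["interpregnancy_interval"] = np.nan
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.as_row()])


@dataclass(frozen=True)
class BiomarkerPanel:
    """Observed first-trimester biomarker values; any subset may be missing
    (``None``/NaN), in which case the marker is dropped from the likelihood."""

    map: Optional[float] = None      # mean arterial pressure, mm Hg
    uta_pi: Optional[float] = None   # mean uterine artery pulsatility index
    plgf: Optional[float] = None     # placental growth factor, pg/mL

    def __post_init__(self):
        for name in MARKERS:
            v = getattr(self, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                if v <= 0:
                    raise ValueError(f"{name} must be positive, got {v}")

    def present(self) -> dict:
        out = {}
        for name in MARKERS:
            v = getattr(self, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                out[name] = float(v)
        return out


def validate_cohort(df: pd.DataFrame, require_outcomes: bool = False) -> list[str]:
    """Row-level validation; returns a list of 'row <i>: <problem>' strings.

    Row numbers are 0-based positions in the frame.
    """
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if require_outcomes:
        missing += [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required columns: {', '.join(missing)}"]
    if len(df) == 0:
        return ["no rows"]

    def flag(mask, msg):
        for i in np.flatnonzero(np.asarray(mask)):
            errors.append(f"row {i}: {msg}")

    num = {c: pd.to_numeric(df[c], errors="coerce") for c in CONTINUOUS_COLUMNS}
    flag(~df["age"].between(12, 60), "age outside [12, 60]")
    flag(~df["weight"].between(30, 250), "weight outside [30, 250]")
    flag(~df["height"].between(120, 210), "height outside [120, 210]")
    flag(~df["ga_screening"].between(11.0, 14.2), "ga_screening outside [11.0, 14.2]")
    for col, levels in CATEGORICAL_LEVELS.items():
        flag(~df[col].isin(levels), f"unknown {col} level")
    flag(~(num["dbp"] >= 50), "dbp below 50 mm Hg")
    flag(~(num["sbp"] <= 260), "sbp above 260 mm Hg")
    flag(~(num["dbp"] < num["sbp"]), "dbp not below sbp")
    flag(~(num["uta_pi"] > 0), "uta_pi not positive")
    flag(~(num["plgf"] > 0), "plgf not positive")
    nulli = df["parity"] == "nulliparous"
    ipi = num["interpregnancy_interval"]
    flag(nulli & ipi.notna(), "interpregnancy_interval present for nulliparous")
    flag(~nulli & ipi.isna(), "interpregnancy_interval missing for parous")
    if require_outcomes or "pe" in df.columns:
        if "pe" in df.columns:
            flag(~df["pe"].isin([0, 1, True, False]), "pe not 0/1")
        if "ga_delivery" in df.columns:
            flag(~pd.to_numeric(df["ga_delivery"], errors="coerce").between(24, 45),
                 "ga_delivery outside [24, 45]")
    return errors
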