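"""Cohort CSV input/output and run manifests.

One canonical comma-separated schema (see :data:`pecrisk.cohort.REQUIRED_COLUMNS`)
with a schema-version header comment on the first line.  Missing values are
empty fields.  Semicolon or locale dialects are rejected, not guessed.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (LATENT_COLUMNS, OUTCOME_COLUMNS, REQUIRED_COLUMNS,
                     validate_cohort)

SCHEMA_HEADER = "# pecrisk-cohort v1"


class CohortValidationError(ValueError):
    """One or more cohort rows failed validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        shown = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} validation problem(s):\n  {shown}{more}")


def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED_COLUMNS + OUTCOME_COLUMNS + LATENT_COLUMNS
            if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df[cols + extra].to_csv(fh, index=False)


def read_cohort(path, skip_invalid: bool = False,
                require_outcomes: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` listing row numbers unless
    ``skip_invalid`` is set, in which case offending rows are dropped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if ";" in first:
        raise CohortValidationError(["semicolon-delimited files are not accepted; "
                                     "use the canonical comma-separated schema"])
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise CohortValidationError(["no rows"]) from None
    if len(df) == 0:
        raise CohortValidationError(["no rows"])
    errors = validate_cohort(df, require_outcomes=require_outcomes)
    if errors:
        if not skip_invalid or errors[0].startswith(("missing", "no rows")):
            raise CohortValidationError(errors)
        bad = sorted({int(e.split(":")[0].split()[1]) for e in errors
                      if e.startswith("row ")})
        df = df.drop(index=df.index[bad]).reset_index(drop=True)
        if len(df) == 0:
            raise CohortValidationError(["no valid rows remain"])
    return df


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted for every pipeline run."""

    command: str
    config_hash: str
    seed: int | None
    policy: str | None
    input_path: str | None
    rows_read: int
    rows_scored: int
    rows_treated: int
    version: str
    timestamp: str

    def __post_init__(self):
        if self.rows_treated > self.rows_scored:
            raise ValueError("treated count exceeds scored count")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def make_manifest(command: str, cfg: dict, *, seed=None, policy=None,
                  input_path=None, rows_read=0, rows_scored=0,
                  rows_treated=0) -> RunManifest:
    return RunManifest(
        command=command, config_hash=config_hash(cfg), seed=seed,
        policy=policy, input_path=str(input_path) if input_path else None,
        rows_read=rows_read, rows_scored=rows_scored, rows_treated=rows_treated,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
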