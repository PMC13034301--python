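"""Expected incidence, risk-reduction metrics and scenario tables.

The expected number of pre-eclampsia cases in a population is the sum of the
per-pregnancy decimal risks.  For an intervention scenario the comparison is
between the expected count without treatment (E_u) and the expected count
with modelled treatment (E_t):

    RRR = 100 (E_u - E_t) / E_u        relative risk reduction, %
    ARR = 100 (E_u - E_t) / n          absolute risk reduction, %
    NNT = n / (E_u - E_t)              number needed to benefit

so ARR x NNT = 100 identically.  All metrics are computed on unrounded sums;
rounding happens only at presentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

BANDS = ("lt32", "lt34", "preterm_lt37", "term_ge37", "all")
_BAND_RISK_COL = {"lt32": "r_lt32", "lt34": "r_lt34", "preterm_lt37": "r_lt37",
                  "term_ge37": "r_term", "all": "r_all"}
_BAND_LABEL = {"lt32": "<32 weeks", "lt34": "<34 weeks",
               "preterm_lt37": "Preterm (<37 weeks)",
               "term_ge37": "Term (>=37 weeks)", "all": "All pre-eclampsia"}


@dataclass(frozen=True)
class ScenarioResult:
    """One band x scope cell of a scenario table (unrounded values)."""

    band: str
    scope: str                   # whole_cohort | treated_subgroup
    n: int
    observed: Optional[int]      # None when outcomes are unavailable
    expected_untreated: float
    expected_treated: float
    rrr: Optional[float]         # %
    arr: float                   # %
    nnt: Optional[float]


def expected_count(risks) -> float:
    """Sum of decimal risks = model-implied number of cases."""
    r = np.asarray(risks, dtype=float)
    if r.size and (np.nanmin(r) < 0 or np.nanmax(r) > 1):
        raise ValueError("risks must lie in [0, 1]")
    return float(np.sum(r))


def percent(count, n) -> float:
    """Share of ``n`` as a percentage rounded to 2 decimal places."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * count / n, 2)


def risk_reduction_metrics(expected_untreated: float, expected_treated: float,
                           n: int):
    """(RRR %, ARR %, NNT) from expected counts; RRR is None when E_u = 0 and
    NNT is None when no cases are averted."""
    if n <= 0:
        raise ValueError("n must be positive")
    if expected_untreated < 0 or expected_treated < 0:
        raise ValueError("expected counts must be non-negative")
    diff = expected_untreated - expected_treated
    rrr = None if expected_untreated == 0 else 100.0 * diff / expected_untreated
    arr = 100.0 * diff / n
    nnt = None if diff == 0 else n / diff
    return rrr, arr, nnt


def observed_band_counts(pe, ga_delivery, band_cuts=(32.0, 34.0, 37.0)) -> dict:
    """Observed case counts per band from the outcome columns."""
    pe = np.asarray(pe, dtype=bool)
    ga = np.asarray(ga_delivery, dtype=float)
    c32, c34, c37 = band_cuts
    return {
        "lt32": int(np.sum(pe & (ga < c32))),
        "lt34": int(np.sum(pe & (ga < c34))),
        "preterm_lt37": int(np.sum(pe & (ga < c37))),
        "term_ge37": int(np.sum(pe & (ga >= c37))),
        "all": int(np.sum(pe)),
    }


def scenario_table(baseline_risks: pd.DataFrame,
                   counterfactual_risks: pd.DataFrame,
                   treated, pe=None, ga_delivery=None,
                   band_cuts=(32.0, 34.0, 37.0)) -> list[ScenarioResult]:
    """Per-band observed / expected / treated-expected summary for the whole
    cohort and the treated subgroup.

    ``baseline_risks`` and ``counterfactual_risks`` are aligned frames from
    :func:`pecrisk.risk_model.score_cohort`; ``treated`` is a boolean array;
    ``pe`` / ``ga_delivery`` supply observed outcomes when available.
    """
    n = len(baseline_risks)
    if len(counterfactual_risks) != n or len(np.asarray(treated)) != n:
        raise ValueError("misaligned scenario inputs")
    treated = np.asarray(treated, dtype=bool)
    have_obs = pe is not None and ga_delivery is not None
    if have_obs and (len(np.asarray(pe)) != n or len(np.asarray(ga_delivery)) != n):
        raise ValueError("misaligned outcome columns")

    results = []
    for scope, mask in (("whole_cohort", np.ones(n, dtype=bool)),
                        ("treated_subgroup", treated)):
        n_scope = int(mask.sum())
        obs = (observed_band_counts(np.asarray(pe)[mask],
                                    np.asarray(ga_delivery)[mask], band_cuts)
               if have_obs and n_scope else {})
        for band in BANDS:
            col = _BAND_RISK_COL[band]
            e_u = expected_count(baseline_risks.loc[mask, col])
            e_t = expected_count(counterfactual_risks.loc[mask, col])
            if n_scope == 0:
                results.append(ScenarioResult(band, scope, 0, obs.get(band),
                                              e_u, e_t, None, 0.0, None))
                continue
            rrr, arr, nnt = risk_reduction_metrics(e_u, e_t, n_scope)
            results.append(ScenarioResult(band, scope, n_scope, obs.get(band),
                                          e_u, e_t, rrr, arr, nnt))
    return results


def scenario_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Presentation frame: counts rounded to integers, percentages to 2 d.p.,
    NNT to 1 d.p.  Unrounded values remain available via the dataclasses."""
    rows = []
    for r in results:
        rows.append({
            "scope": r.scope,
            "band": r.band,
            "n": r.n,
            "observed": r.observed,
            "observed_pct": percent(r.observed, r.n) if r.observed is not None and r.n else None,
            "expected": round(r.expected_untreated),
            "expected_pct": percent(r.expected_untreated, r.n) if r.n else None,
            "treated_expected": round(r.expected_treated),
            "treated_pct": percent(r.expected_treated, r.n) if r.n else None,
            "rrr_pct": None if r.rrr is None else round(r.rrr, 2),
            "arr_pct": round(r.arr, 2),
            "nnt": None if r.nnt is None else round(r.nnt, 1),
        })
    return pd.DataFrame(rows)


def scenario_json(results: list[ScenarioResult], **meta) -> str:
    """JSON summary with unrounded values."""
    payload = dict(meta)
    payload["cells"] = [asdict(r) for r in results]
    return json.dumps(payload, indent=2)


def render_text_table(results: list[ScenarioResult], title: str = "") -> str:
    """Aligned text table mirroring the published scenario-table layout
    (rows = bands, columns = observed / expected / treated / RRR)."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    for scope in ("whole_cohort", "treated_subgroup"):
        cells = {r.band: r for r in results if r.scope == scope}
        if not cells:
            continue
        n = next(iter(cells.values())).n
        lines.append(f"\n{scope.replace('_', ' ').title()} (n={n})")
        hdr = f"{'Pre-eclampsia type':<22}{'Observed':>12}{'Expected':>12}{'Treated':>12}{'RRR %':>9}{'NNT':>9}"
        lines += [hdr, "-" * len(hdr)]
        for band in BANDS:
            r = cells[band]
            obs = "-" if r.observed is None else str(r.observed)
            rrr = "-" if r.rrr is None else f"{r.rrr:.2f}"
            nnt = "-" if r.nnt is None else f"{r.nnt:.1f}"
            lines.append(f"{_BAND_LABEL[r.band]:<22}{obs:>12}"
                         f"{r.expected_untreated:>12.0f}{r.expected_treated:>12.0f}"
                         f"{rrr:>9}{nnt:>9}")
    return "\n".join(lines) + "\n"
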