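"""Personalised competing-risks pre-eclampsia risk.

The model places a Gaussian prior on ``G``, the gestational age at which
delivery with pre-eclampsia would occur if no other delivery intervened:

    G ~ Normal(mu, sigma^2),   mu = mu0 + sum(covariate effects)

conditioned on ``G >= g_min`` (the cohort contains only births at >= 24
weeks).  Biomarkers enter as a multivariate-Gaussian likelihood on log10
multiples of the median whose mean depends piecewise-linearly on ``G``:
earlier pre-eclampsia means higher MAP and UtA-PI MoM and lower PlGF MoM.
The posterior is evaluated on a discrete grid over ``[g_min, g_max]`` plus a
censored atom for ``G > g_max`` ("pregnancy delivers before pre-eclampsia
develops"); band risks are posterior masses below the clinical cut-offs
(<32, <34, <37 weeks), at term (37 to g_max), and overall.

Grid cells carry exact prior Normal cell masses (CDF differences) with the
likelihood evaluated at cell midpoints, so with a flat likelihood the prior
band masses are recovered to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import MARKERS, BiomarkerPanel, MaternalProfile
from .params import RiskModelParams, evaluate_effects

__all__ = [
    "GARiskProfile", "prior_ga_mean", "expected_log10_marker", "compute_mom",
    "log10_mom", "posterior_ga_distribution", "band_risks", "score_cohort",
    "risk_profile_vs_dbp",
]

_CHUNK = 8192


@dataclass(frozen=True)
class GARiskProfile:
    """Posterior over gestational age at delivery with pre-eclampsia."""

    grid_mid: np.ndarray      # cell midpoints, weeks
    density: np.ndarray       # probability mass per cell
    p_beyond: float           # mass at G > g_max (no pre-eclampsia)
    r_lt32: float = np.nan
    r_lt34: float = np.nan
    r_lt37: float = np.nan
    r_term: float = np.nan
    r_all: float = np.nan

    @property
    def mean(self) -> float:
        """Posterior mean of G restricted to the grid (excluding the atom)."""
        m = self.density.sum()
        return float(np.dot(self.grid_mid, self.density) / m) if m > 0 else np.nan


def grid_edges(params: RiskModelParams) -> np.ndarray:
    n = int(round((params.grid_max - params.grid_min) / params.grid_step))
    return params.grid_min + params.grid_step * np.arange(n + 1)


def prior_ga_mean(profile, params: RiskModelParams):
    """Prior mean gestational age at delivery with pre-eclampsia (weeks).

    ``profile`` may be a :class:`MaternalProfile` or a cohort frame; the
    result is a float or an array accordingly.
    """
    single = isinstance(profile, MaternalProfile)
    df = profile.to_frame() if single else profile
    mu = params.prior_intercept + evaluate_effects(df, params.prior_effects)
    return float(mu[0]) if single else mu


def expected_log10_marker(marker_id: str, profile, params: RiskModelParams):
    """Expected log10 marker value (the MoM denominator) for the covariates."""
    if marker_id not in MARKERS:
        raise KeyError(f"unknown marker {marker_id!r}; expected one of {MARKERS}")
    m = params.markers[marker_id]
    single = isinstance(profile, MaternalProfile)
    df = profile.to_frame() if single else profile
    v = m.intercept_log10 + evaluate_effects(df, m.regression)
    return float(v[0]) if single else v


def compute_mom(observed, expected_log10):
    """Multiple of the median: observed / 10**expected_log10."""
    observed = np.asarray(observed, dtype=float)
    if np.any(observed <= 0):
        raise ValueError("observed marker values must be positive")
    out = observed / np.power(10.0, np.asarray(expected_log10, dtype=float))
    return float(out) if out.ndim == 0 else out


def log10_mom(observed, expected_log10):
    """log10 MoM = log10(observed) - expected_log10."""
    observed = np.asarray(observed, dtype=float)
    if np.any(observed <= 0):
        raise ValueError("observed marker values must be positive")
    out = np.log10(observed) - np.asarray(expected_log10, dtype=float)
    return float(out) if out.ndim == 0 else out


def _prior_masses(mu, params: RiskModelParams):
    """Exact Normal cell masses and beyond-grid atom, conditioned on
    G >= g_min.  ``mu`` is an array of shape (n,); returns (n, ncells) and
    (n,)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    edges = grid_edges(params)
    cdf = norm.cdf((edges[None, :] - mu) / params.prior_sd)
    total = 1.0 - cdf[:, 0]
    if np.any(total <= 0):
        raise ValueError("prior has no mass at or beyond g_min")
    cells = np.diff(cdf, axis=1) / total[:, None]
    beyond = (1.0 - cdf[:, -1]) / total
    return cells, beyond


def _marker_mean_matrix(params: RiskModelParams, names) -> np.ndarray:
    """Mean log10 MoM at each grid midpoint plus the censored atom (mean 0);
    shape (ncells + 1, len(names))."""
    edges = grid_edges(params)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cols = [params.markers[n].mean_log10_mom(mids) for n in names]
    M = np.column_stack(cols) if cols else np.empty((len(mids), 0))
    return np.vstack([M, np.zeros((1, len(names)))])


def _posterior_weights(mu, x, params: RiskModelParams, names):
    """Posterior mass over (grid cells + atom) for rows with marker set
    ``names`` and observed log10 MoMs ``x`` (n, k)."""
    cells, beyond = _prior_masses(mu, params)
    logw = np.log(np.hstack([cells, beyond[:, None]]) + 1e-300)
    if names:
        P = np.linalg.inv(params.sub_cov(names))
        M = _marker_mean_matrix(params, names)          # (G+1, k)
        xP = x @ P                                      # (n, k)
        quad = (np.einsum("ij,ij->i", xP, x)[:, None]
                - 2.0 * xP @ M.T
                + np.einsum("ij,ij->i", M @ P, M)[None, :])
        logw = logw - 0.5 * quad
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w[:, :-1], w[:, -1]


def band_risks(profile: GARiskProfile, params: RiskModelParams) -> GARiskProfile:
    """Fill in band risks from a (normalised) grid density.

    ``r_lt{c}`` is the mass strictly below cut ``c`` (cells straddling a cut
    contribute the fraction of their width below it); ``r_term`` is the mass
    in ``[37, g_max]``; ``r_all = r_lt37 + r_term``; the beyond-grid atom
    counts as "no pre-eclampsia".
    """
    edges = grid_edges(params)
    cum = np.concatenate([[0.0], np.cumsum(profile.density)])

    def mass_below(cut):
        pos = (cut - params.grid_min) / params.grid_step
        j = int(np.floor(pos + 1e-9))
        j = min(max(j, 0), len(profile.density))
        frac = pos - j
        extra = frac * profile.density[j] if 0 < frac and j < len(profile.density) else 0.0
        return float(cum[j] + extra)

    c32, c34, c37 = params.band_cuts
    r_all = float(profile.density.sum())
    r37 = mass_below(c37)
    return replace(profile, r_lt32=mass_below(c32), r_lt34=mass_below(c34),
                   r_lt37=r37, r_term=r_all - r37, r_all=r_all)


def posterior_ga_distribution(mu: float, params: RiskModelParams,
                              log10_moms: dict | None = None) -> GARiskProfile:
    """Posterior over G for one pregnancy given a partial map of observed
    log10 MoMs (missing markers are marginalised out)."""
    log10_moms = log10_moms or {}
    names = [m for m in MARKERS if m in log10_moms]
    x = np.array([[log10_moms[n] for n in names]], dtype=float)
    dens, beyond = _posterior_weights(np.array([mu]), x, params, names)
    edges = grid_edges(params)
    prof = GARiskProfile(grid_mid=0.5 * (edges[:-1] + edges[1:]),
                         density=dens[0], p_beyond=float(beyond[0]))
    return band_risks(prof, params)


def _cohort_log10_moms(df: pd.DataFrame, params: RiskModelParams,
                       map_values=None) -> np.ndarray:
    """(n, 3) array of observed log10 MoMs in marker order; NaN = missing.

    MAP is derived from the stored systolic/diastolic pair unless explicit
    ``map_values`` are given (the counterfactual path); the MoM denominator
    always uses the covariate regression, never the intervention.
    """
    n = len(df)
    out = np.full((n, 3), np.nan)
    if map_values is None:
        sbp = pd.to_numeric(df["sbp"], errors="coerce").to_numpy(float)
        dbp = pd.to_numeric(df["dbp"], errors="coerce").to_numpy(float)
        map_values = (sbp + 2.0 * dbp) / 3.0
    else:
        map_values = np.asarray(map_values, dtype=float)
    obs = {"map": map_values,
           "uta_pi": pd.to_numeric(df["uta_pi"], errors="coerce").to_numpy(float),
           "plgf": pd.to_numeric(df["plgf"], errors="coerce").to_numpy(float)}
    for j, name in enumerate(MARKERS):
        v = obs[name]
        ok = np.isfinite(v)
        if np.any(v[ok] <= 0):
            raise ValueError(f"non-positive {name} value in cohort")
        exp10 = expected_log10_marker(name, df, params)
        out[ok, j] = np.log10(v[ok]) - np.asarray(exp10)[ok]
    return out


def score_cohort(df: pd.DataFrame, params: RiskModelParams,
                 map_values=None) -> pd.DataFrame:
    """Band risks for every pregnancy in the cohort.

    Returns a frame indexed like ``df`` with columns ``r_lt32, r_lt34,
    r_lt37, r_term, r_all`` (and ``post_mean``, the posterior mean of G on
    the grid).  Rows are grouped by biomarker-missingness pattern and scored
    in vectorised chunks.
    """
    mu = np.asarray(prior_ga_mean(df, params), dtype=float)
    X = _cohort_log10_moms(df, params, map_values=map_values)
    present = np.isfinite(X)
    edges = grid_edges(params)
    mids = 0.5 * (edges[:-1] + edges[1:])
    ncells = len(mids)
    cut_idx = {}
    for c in params.band_cuts:
        pos = (c - params.grid_min) / params.grid_step
        cut_idx[c] = (int(np.floor(pos + 1e-9)), pos)

    res = np.empty((len(df), 6))
    patterns = {}
    for i, row in enumerate(present):
        patterns.setdefault(tuple(row), []).append(i)
    for pat, idx in patterns.items():
        idx = np.asarray(idx)
        names = [m for m, p in zip(MARKERS, pat) if p]
        cols = [j for j, p in enumerate(pat) if p]
        for lo in range(0, len(idx), _CHUNK):
            sl = idx[lo:lo + _CHUNK]
            dens, beyond = _posterior_weights(mu[sl], X[np.ix_(sl, cols)],
                                              params, names)
            cum = np.concatenate([np.zeros((len(sl), 1)),
                                  np.cumsum(dens, axis=1)], axis=1)
            r_all = cum[:, -1]
            band = []
            for c in params.band_cuts:
                j, pos = cut_idx[c]
                frac = pos - j
                v = cum[:, j]
                if frac > 1e-9 and j < ncells:
                    v = v + frac * dens[:, j]
                band.append(v)
            r37 = band[2]
            post_mean = np.where(r_all > 0, dens @ mids / np.maximum(r_all, 1e-300),
                                 np.nan)
            res[sl, 0] = band[0]
            res[sl, 1] = band[1]
            res[sl, 2] = r37
            res[sl, 3] = r_all - r37
            res[sl, 4] = r_all
            res[sl, 5] = post_mean
    return pd.DataFrame(res, index=df.index,
                        columns=["r_lt32", "r_lt34", "r_lt37", "r_term",
                                 "r_all", "post_mean"])


def risk_profile_vs_dbp(profile: MaternalProfile, panel: BiomarkerPanel,
                        dbp_values, params: RiskModelParams,
                        baseline_sbp: float | None = None,
                        baseline_dbp: float | None = None,
                        sbp_ratio: float = 5.8 / 4.6) -> pd.DataFrame:
    """Overall pre-eclampsia risk as diastolic pressure varies.

    Systolic pressure co-varies with the diastolic change at ``sbp_ratio``
    mm Hg per mm Hg around the baseline blood-pressure pair (defaults:
    baseline MAP from ``panel.map`` with sbp/dbp split 121/70 if no pair is
    supplied).  Returns a frame of (dbp, map, r_all).
    """
    dbp_values = np.asarray(dbp_values, dtype=float)
    if np.any(np.diff(dbp_values) < 0):
        raise ValueError("dbp_values must be non-decreasing")
    if baseline_dbp is None or baseline_sbp is None:
        if panel.map is None:
            raise ValueError("need either a baseline sbp/dbp pair or panel.map")
        baseline_dbp = (3.0 * panel.map - 121.0) / 2.0 if baseline_dbp is None else baseline_dbp
        baseline_sbp = 3.0 * panel.map - 2.0 * baseline_dbp
    mu = prior_ga_mean(profile, params)
    fixed = {}
    for name in ("uta_pi", "plgf"):
        v = getattr(panel, name)
        if v is not None and np.isfinite(v):
            fixed[name] = log10_mom(v, expected_log10_marker(name, profile, params))
    exp_map = expected_log10_marker("map", profile, params)
    rows = []
    for d in dbp_values:
        s = baseline_sbp - sbp_ratio * (baseline_dbp - d)
        m = (s + 2.0 * d) / 3.0
        moms = dict(fixed)
        moms["map"] = log10_mom(m, exp_map)
        prof = posterior_ga_distribution(mu, params, moms)
        rows.append((d, m, prof.r_all))
    return pd.DataFrame(rows, columns=["dbp", "map", "r_all"])
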