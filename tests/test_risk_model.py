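"""Competing-risks posterior: priors, MoM machinery, band risks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from pecrisk.cohort import MARKERS, BiomarkerPanel, MaternalProfile, UnknownLevelError
from pecrisk.risk_model import (GARiskProfile, band_risks, compute_mom,
                                expected_log10_marker, grid_edges, log10_mom,
                                posterior_ga_distribution, prior_ga_mean,
                                risk_profile_vs_dbp, score_cohort)


# ---------------------------------------------------------------- prior mean

def test_prior_mean_reference_is_intercept(make_params, reference_profile):
    p = make_params(mu0=52.0)
    assert prior_ga_mean(reference_profile, p) == pytest.approx(52.0)


def test_prior_mean_additive_and_commutative(make_params):
    p = make_params(mu0=52.0, effects={
        "chronic_hypertension": -8.0,
        "ethnic_group": {"black": -3.0},
        "smoker": -2.0,
    })
    assert prior_ga_mean(
        MaternalProfile.reference(chronic_hypertension=True), p) == pytest.approx(44.0)
    # two effects add in either declaration order
    both = MaternalProfile.reference(ethnic_group="black", smoker=True)
    assert prior_ga_mean(both, p) == pytest.approx(52.0 - 3.0 - 2.0)
    p2 = make_params(mu0=52.0, effects={
        "smoker": -2.0, "ethnic_group": {"black": -3.0}})
    assert prior_ga_mean(both, p2) == pytest.approx(47.0)


def test_prior_mean_rejects_unknown_level(make_params):
    p = make_params(effects={"ethnic_group": {"black": -3.0}})
    df = MaternalProfile.reference().to_frame()
    df.loc[0, "ethnic_group"] = "martian"
    with pytest.raises(UnknownLevelError, match="martian"):
        prior_ga_mean(df, p)


# ------------------------------------------------------------- MoM machinery

def test_expected_log10_marker_intercept_and_linearity(params, reference_profile):
    # the reference woman sits at every centring point, so only the
    # intercept contributes
    v_ref = expected_log10_marker("map", reference_profile, params)
    assert v_ref == pytest.approx(params.markers["map"].intercept_log10, abs=1e-9)
    heavier = MaternalProfile.reference(weight=79.0)
    c = params.markers["map"].regression["weight"]["per_unit"]
    assert expected_log10_marker("map", heavier, params) - v_ref == pytest.approx(10 * c)
    # round trip: observing the expected median gives MoM exactly 1
    assert compute_mom(10.0 ** v_ref, v_ref) == pytest.approx(1.0)
    with pytest.raises(KeyError):
        expected_log10_marker("afp", reference_profile, params)


@pytest.mark.parametrize("observed,expected_log10,mom", [
    (85.0, np.log10(85.0), 1.0),
    (170.0, np.log10(85.0), 2.0),
])
def test_compute_mom(observed, expected_log10, mom):
    assert compute_mom(observed, expected_log10) == pytest.approx(mom)
    assert log10_mom(observed, expected_log10) == pytest.approx(np.log10(mom))


def test_compute_mom_rejects_nonpositive():
    with pytest.raises(ValueError):
        compute_mom(0.0, 1.0)
    with pytest.raises(ValueError):
        compute_mom(-3.0, 1.0)


# ------------------------------------------------------ posterior behaviour

def _closed_form_prior_bands(mu, p):
    z = lambda g: norm.cdf((g - mu) / p.prior_sd)  # noqa: E731
    tot = 1.0 - z(p.grid_min)
    return {c: (z(c) - z(p.grid_min)) / tot for c in (*p.band_cuts, p.grid_max)}


def test_prior_recovery_no_markers(make_params):
    """Flat likelihood: posterior band risks equal closed-form Gaussian
    masses to 1e-6."""
    p = make_params(mu0=47.0, sd=5.0)
    prof = posterior_ga_distribution(47.0, p, {})
    want = _closed_form_prior_bands(47.0, p)
    assert prof.r_lt32 == pytest.approx(want[32.0], abs=1e-6)
    assert prof.r_lt34 == pytest.approx(want[34.0], abs=1e-6)
    assert prof.r_lt37 == pytest.approx(want[37.0], abs=1e-6)
    assert prof.r_all == pytest.approx(want[42.0], abs=1e-6)


def test_zero_slopes_ignore_markers(make_params):
    p = make_params(mu0=50.0, sd=4.0, slopes=(0.0, 0.0, 0.0))
    flat = posterior_ga_distribution(50.0, p, {})
    loaded = posterior_ga_distribution(50.0, p, {"map": 0.4, "uta_pi": -0.3, "plgf": 0.2})
    np.testing.assert_allclose(loaded.density, flat.density, atol=1e-12)
    assert loaded.r_all == pytest.approx(flat.r_all, abs=1e-12)


def test_positive_map_mom_pulls_posterior_earlier(params):
    """With a negative MAP slope, an elevated MAP MoM shifts mass to earlier
    gestations; checked against brute-force integration at step/10."""
    mu = 50.0
    fine = dataclasses.replace(params, grid_step=params.grid_step / 10)
    post = posterior_ga_distribution(mu, fine, {"map": 0.05})
    prior = posterior_ga_distribution(mu, fine, {})
    assert post.mean < prior.mean
    assert post.mean < mu
    coarse = posterior_ga_distribution(mu, params, {"map": 0.05})
    assert coarse.mean == pytest.approx(post.mean, abs=1e-3)


def test_missing_markers_are_marginalised(params):
    """A partial panel uses only the sub-covariance of the present markers."""
    full = posterior_ga_distribution(48.0, params, {"map": 0.03, "plgf": -0.2})
    only_map = posterior_ga_distribution(48.0, params, {"map": 0.03})
    assert full.r_all != pytest.approx(only_map.r_all, abs=1e-6)
    assert abs(full.density.sum() + full.p_beyond - 1) < 1e-9


_DEFAULTS = None


def _defaults():
    global _DEFAULTS
    if _DEFAULTS is None:
        from pecrisk.params import default_params
        _DEFAULTS = default_params()
    return _DEFAULTS


@settings(max_examples=50, derandomize=True, deadline=None)
@given(mu=st.floats(34.0, 60.0),
       m_map=st.floats(-0.15, 0.15), m_pi=st.floats(-0.5, 0.5),
       m_plgf=st.floats(-0.7, 0.7))
def test_posterior_normalisation_and_band_nesting(mu, m_map, m_pi, m_plgf):
    prof = posterior_ga_distribution(mu, _defaults(), {"map": m_map,
                                                       "uta_pi": m_pi,
                                                       "plgf": m_plgf})
    assert abs(prof.density.sum() + prof.p_beyond - 1.0) < 1e-9
    assert 0.0 <= prof.r_lt32 <= prof.r_lt34 <= prof.r_lt37 <= prof.r_all <= 1.0
    assert prof.r_all == pytest.approx(prof.r_lt37 + prof.r_term, abs=1e-9)


def test_grid_convergence(params):
    prof = posterior_ga_distribution(46.0, params, {"map": 0.04, "plgf": -0.3})
    halved = dataclasses.replace(params, grid_step=params.grid_step / 2)
    prof2 = posterior_ga_distribution(46.0, halved, {"map": 0.04, "plgf": -0.3})
    assert abs(prof.r_all - prof2.r_all) < 1e-4


def _quad_band_risks(mu, p, moms):
    """Independent adaptive-quadrature oracle for the posterior band risks."""
    names = [m for m in MARKERS if m in moms]
    x = np.array([moms[n] for n in names])
    P = np.linalg.inv(p.sub_cov(names))

    def lik(g):
        m = np.array([p.markers[n].mean_log10_mom(g) for n in names])
        d = x - m
        return float(np.exp(-0.5 * d @ P @ d))

    def f(g):
        return norm.pdf(g, mu, p.prior_sd) * lik(g)

    pieces = [quad(f, a, b, limit=200)[0] for a, b in
              zip((p.grid_min, *p.band_cuts), (*p.band_cuts, p.grid_max))]
    beyond = (1.0 - norm.cdf((p.grid_max - mu) / p.prior_sd)) * lik(p.grid_max + 1.0)
    Z = sum(pieces) + beyond
    cum = np.cumsum(pieces) / Z
    return {"r_lt32": cum[0], "r_lt34": cum[1], "r_lt37": cum[2], "r_all": cum[3]}


def test_grid_matches_quadrature_oracle(make_params):
    """Grid posterior band risks agree with adaptive quadrature to 1e-5 on
    20 random parameter draws."""
    rng = np.random.default_rng(2024)
    for _ in range(20):
        p = make_params(mu0=float(rng.uniform(38, 58)),
                        sd=float(rng.uniform(2.0, 10.0)),
                        slopes=tuple(rng.uniform(-0.05, 0.05, 3)),
                        changepoints=tuple(rng.uniform(34, 42, 3)))
        moms = {"map": float(rng.normal(0, 0.05)),
                "uta_pi": float(rng.normal(0, 0.15)),
                "plgf": float(rng.normal(0, 0.2))}
        prof = posterior_ga_distribution(p.prior_intercept, p, moms)
        want = _quad_band_risks(p.prior_intercept, p, moms)
        for key, val in want.items():
            assert getattr(prof, key) == pytest.approx(val, abs=1e-5), key


def test_map_mom_monotonicity(params):
    """Under defaults, a higher MAP MoM strictly increases preterm risk."""
    risks = [posterior_ga_distribution(50.0, params, {"map": m}).r_lt37
             for m in (-0.05, 0.0, 0.05, 0.10)]
    assert all(a < b for a, b in zip(risks, risks[1:]))


# ------------------------------------------------------------- band examples

def _point_mass_profile(params, g):
    edges = grid_edges(params)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dens = np.zeros(len(mids))
    dens[np.searchsorted(edges, g) - 1] = 1.0
    return GARiskProfile(grid_mid=mids, density=dens, p_beyond=0.0)


def test_band_risks_point_mass_at_30(params):
    prof = band_risks(_point_mass_profile(params, 30.0), params)
    assert (prof.r_lt32, prof.r_lt34, prof.r_lt37, prof.r_all) == (1, 1, 1, 1)
    assert prof.r_term == 0


def test_band_risks_all_mass_beyond_gmax(params):
    edges = grid_edges(params)
    mids = 0.5 * (edges[:-1] + edges[1:])
    prof = band_risks(GARiskProfile(grid_mid=mids, density=np.zeros(len(mids)),
                                    p_beyond=1.0), params)
    assert prof.r_all == 0 and prof.r_lt37 == 0 and prof.r_term == 0


def test_band_risks_uniform_36_38(params):
    edges = grid_edges(params)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dens = np.where((mids > 36.0) & (mids < 38.0), 1.0, 0.0)
    dens /= dens.sum()
    prof = band_risks(GARiskProfile(grid_mid=mids, density=dens, p_beyond=0.0),
                      params)
    assert prof.r_lt37 == pytest.approx(0.5, abs=1e-9)
    assert prof.r_term == pytest.approx(0.5, abs=1e-9)
    assert prof.r_all == pytest.approx(1.0, abs=1e-12)


# -------------------------------------------------------- risk vs dbp curves

def test_risk_vs_dbp_flat_when_uninformative(make_params, reference_profile):
    p = make_params(slopes=(0.0, 0.0, 0.0))
    panel = BiomarkerPanel(uta_pi=1.65, plgf=38.0)
    out = risk_profile_vs_dbp(reference_profile, panel, np.arange(70, 101, 5), p,
                              baseline_sbp=120.0, baseline_dbp=80.0)
    assert np.ptp(out["r_all"].to_numpy()) < 1e-12


def test_risk_vs_dbp_profiles_ordered_and_consistent(params):
    """A high-risk profile sits pointwise above a low-risk one, and the curve
    agrees with the standard scoring pipeline at each dbp."""
    low = MaternalProfile.reference()
    high = MaternalProfile.reference(chronic_hypertension=True,
                                     parity="parous_prior_pe",
                                     interpregnancy_interval=2.9, weight=95.0)
    panel = BiomarkerPanel(uta_pi=1.9, plgf=30.0)
    dbp = np.arange(70.0, 101.0, 5.0)
    out_low = risk_profile_vs_dbp(low, panel, dbp, params,
                                  baseline_sbp=125.0, baseline_dbp=82.0)
    out_high = risk_profile_vs_dbp(high, panel, dbp, params,
                                   baseline_sbp=125.0, baseline_dbp=82.0)
    assert (out_high["r_all"].to_numpy() > out_low["r_all"].to_numpy()).all()
    assert (np.diff(out_low["r_all"]) >= 0).all()  # risk rises with dbp
    # single-point consistency with posterior_ga_distribution
    row = out_high.iloc[2]
    from pecrisk.risk_model import expected_log10_marker as exp10
    moms = {"map": log10_mom(row["map"], exp10("map", high, params)),
            "uta_pi": log10_mom(1.9, exp10("uta_pi", high, params)),
            "plgf": log10_mom(30.0, exp10("plgf", high, params))}
    direct = posterior_ga_distribution(prior_ga_mean(high, params), params, moms)
    assert row["r_all"] == pytest.approx(direct.r_all, abs=1e-12)


# ------------------------------------------------------------ cohort scoring

def test_score_cohort_matches_single_row_path(small_cohort):
    df, gc = small_cohort
    p = gc.risk_model
    risks = score_cohort(df, p)
    i = int(np.argmax(df["dbp"].to_numpy()))  # a high-risk row
    row = df.iloc[[i]]
    mu = prior_ga_mean(row, p)[0]
    moms = {}
    map_obs = (row["sbp"].iloc[0] + 2 * row["dbp"].iloc[0]) / 3
    for name, obs in (("map", map_obs), ("uta_pi", row["uta_pi"].iloc[0]),
                      ("plgf", row["plgf"].iloc[0])):
        moms[name] = log10_mom(obs, expected_log10_marker(name, row, p)[0])
    prof = posterior_ga_distribution(mu, p, moms)
    assert risks["r_all"].iloc[i] == pytest.approx(prof.r_all, abs=1e-12)
    assert risks["r_lt37"].iloc[i] == pytest.approx(prof.r_lt37, abs=1e-12)


def test_score_cohort_handles_missing_markers(small_cohort):
    df, gc = small_cohort
    df = df.copy()
    df.loc[df.index[:50], "plgf"] = np.nan
    df.loc[df.index[25:75], "uta_pi"] = np.nan
    risks = score_cohort(df, gc.risk_model)
    assert np.isfinite(risks["r_all"]).all()
    assert ((risks["r_all"] >= 0) & (risks["r_all"] <= 1)).all()
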