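# Methods

`pecrisk` models what would happen to the incidence of pre-eclampsia (PE) in
a first-trimester screening population if raised diastolic blood pressure
were lowered pharmacologically from 11–13 weeks' gestation.  It combines a
competing-risks PE risk model, a counterfactual blood-pressure intervention,
incidence arithmetic (relative/absolute risk reduction, number needed to
benefit), calibration diagnostics, and a synthetic-cohort generator that
makes the whole pipeline testable without access to any study data.

## The competing-risks risk model

Let `G` be the gestational age (weeks) at which delivery with pre-eclampsia
would occur if no other delivery intervened.  The working assumption is that
every pregnancy would eventually develop pre-eclampsia if it continued
indefinitely; whether PE is observed depends on the competition between `G`
and delivery from other causes.  The model is

    G ~ Normal(mu, sigma^2),  conditioned on G >= g_min
    mu = mu0 + sum of additive covariate effects (weeks)

Risk-increasing history (chronic hypertension, previous pre-eclampsia,
SLE/APS, diabetes, higher weight, Black ethnicity, assisted conception,
family history, nulliparity) shifts `mu` to the left — earlier PE, higher
risk; protective factors (taller stature, smoking) shift it right.  Effects
are declared in a YAML configuration (linear terms with documented centring
points, one-sided hinge terms, categorical offsets from a reference level:
White ethnicity, parous without previous PE).

Biomarkers enter as a Bayesian update.  Each marker k in {MAP, UtA-PI, PlGF}
is reduced to a log10 multiple of the median (MoM): the observed value
divided by the median expected for the woman's covariates, from a log10-
linear regression.  Given `G = g`, the vector of log10 MoMs is multivariate
Gaussian with covariance `Sigma` (3x3) and piecewise-linear mean

    m_k(g) = b_k * (g - g0_k)  for g < g0_k,   0 otherwise.

With `b_MAP, b_UtA-PI < 0` and `b_PlGF > 0`, earlier pre-eclampsia implies
higher MAP and UtA-PI MoM and lower PlGF MoM, vanishing at the changepoint
`g0_k`.  Missing markers are marginalised out (the likelihood uses the
sub-covariance of the observed markers); nothing is imputed.

The posterior over `G` is evaluated on a grid over `[g_min, g_max]`
(defaults 24–42 weeks, step 0.025) plus a censored atom for `G > g_max`,
whose likelihood uses the mean-zero regime (all default changepoints are
<= g_max, so the atom is exact).  Grid cells carry exact Normal cell masses
(CDF differences) with the likelihood at cell midpoints; with a flat
likelihood the prior band masses are therefore recovered to machine
precision, and halving the step changes the overall risk by < 1e-4.  Band
risks are posterior masses: `r_lt32`, `r_lt34`, `r_lt37` below the clinical
cut-offs, `r_term` in `[37, g_max]`, and `r_all = r_lt37 + r_term`; the atom
counts as "no pre-eclampsia".

Numerical choices: posteriors are normalised in log space (log-sum-exp);
cells straddling a band cut contribute the fraction of their width below the
cut; the per-marker sub-covariance must stay positive definite (validated at
load).  An adaptive-quadrature implementation of the same integrals is kept
in the test suite as an independent oracle (agreement to 1e-5).

## Coefficients are configurable, defaults are synthetic

The published first-trimester competing-risks screening model's coefficient
values are proprietary and are not reproduced here.  All coefficients live
in `src/pecrisk/data/default_params.yaml`; the shipped defaults are the
package's own synthetic choices, fixed once by moment-matching so that the
default generator reproduces population-scale anchors: ~0.83% preterm,
~2.09% term and ~2.93% overall pre-eclampsia; diastolic-pressure subgroup
fractions near 1.6 / 4.8 / 13.2 / 29.5% above 90 / 85 / 80 / 75 mm Hg; and
ACC/AHA blood-pressure strata near 60 / 21 / 16 / 3%.  The prior intercept
(62.34 weeks) and sd (9.59 weeks) were solved jointly against the first two
anchors given the covariate effects; the blood-pressure model (systolic
intercept 30 mm Hg, slope 1.0 per MAP mm Hg, noise sd 8 mm Hg; MAP residual
sd 0.030 log10) against the last two.  Likelihood slopes (-0.004, -0.025,
+0.030 log10 MoM/week for MAP, UtA-PI, PlGF; changepoints 40 weeks) give
marker deviations of realistic size for early PE (e.g. UtA-PI MoM ~1.8 at
30 weeks).  Conclusions drawn with these defaults are about the method, not
about any real population.

## The counterfactual intervention

A policy is a threshold/target pair `(T, t)`, `t <= T`: women with diastolic
pressure strictly above `T` are treated and their modelled attained
diastolic pressure equals `t`.  Four named policies are built in:
current-care (90→85) and the threshold-equals-target policies t85, t80, t75.
Systolic pressure falls with the diastolic reduction,

    sbp' = sbp - rho * (dbp - t),    rho default 5.8/4.6 = 1.26,

the systolic/diastolic reduction ratio achieved in the CHIPS trial.  The
systolic value is floored at `t + 5` mm Hg but never raised above its
pre-treatment value, so treated MAP strictly decreases; when both guards
conflict (possible only for sbp < 80 under t75) the physiological ordering
wins and a warning is logged.  Treatment is idempotent.  MAP is recomputed
from the capped pair and the model re-scored; the MoM denominator keeps the
pre-treatment covariate regression — the intervention changes the observed
pressure, not the woman's expected median.

An optional stochastic systolic term is deliberately not enabled by default:
the deterministic linear reduction keeps scenario runs reproducible and the
policy-dominance property provable.

## Incidence, RRR, ARR, NNT

The expected number of cases in any group is the sum of the per-pregnancy
decimal band risks.  For expected counts E_u (untreated) and E_t (treated)
over n pregnancies:

    RRR = 100 (E_u - E_t) / E_u,  ARR = 100 (E_u - E_t) / n,  NNT = n / (E_u - E_t)

so `ARR x NNT = 100` identically, and the whole-cohort absolute reduction
equals the treated-subgroup reduction exactly (untreated rows contribute
zero difference).  All metrics are computed on unrounded sums; rounding
(counts to integers, percentages to 2 d.p., NNT to 1 d.p.) happens only at
presentation.  Note that published tables of this design sometimes describe
the RRR as treated-vs-observed while the printed values reproduce from
treated-vs-expected; this package uses the expected-vs-treated ratio
throughout, which is also the internally consistent choice
(`ARR x NNT = 100`).

Observed band assignment uses delivery gestation: preterm PE iff delivery
< 37.0 weeks.

## Calibration

Predicted risks `r` are compared with outcomes `y` by equal-count bins
(default 10, ties broken by stable input order) and two logistic summaries
on the logit scale: the calibration intercept alpha (intercept-only
Bernoulli fit with `logit(r)` as fixed offset; 0 = perfect
calibration-in-the-large) and the calibration slope beta (two-parameter fit;
1 = perfect spread).  Individual-level regression is used, not binned.
Fits use iteratively reweighted least squares (statsmodels GLM, Binomial
family, tolerance 1e-8); risks are clipped to `[1e-8, 1 - 1e-8]` before the
logit and clipping is logged; complete separation (all events or none) is
signalled, not estimated.

## The synthetic-cohort generator

The generator draws, per pregnancy and in this order: covariates (marginals
configured to a large UK screening population: ethnic mix 72/17/6/2/3%,
median age 31, median BMI 24.7 with log-normal skew, weight–height Gaussian
copula at correlation 0.4, parity 47/50/3%, chronic hypertension 1.34%,
etc.); the prior mean `mu`; the latent PE delivery age `g_pe ~ Normal(mu,
sigma)` truncated to `[g_min, inf)` (the cohort contains only births >= 24
weeks, and the scorer conditions on the same event); log10 MoMs from the
model's own likelihood at `g_pe`; raw markers as MoM times the covariate
median; systolic pressure from the generated MAP (`sbp = 30 + MAP +
Normal(0, 8)`), with diastolic closing the identity `MAP = (sbp + 2 dbp)/3`
exactly, so scoring inverts the generative process without approximation
(diastolic values are floored at 50 mm Hg with the identity preserved); an
other-cause delivery age from a truncated Normal (mean 40.0, sd 1.4, range
24–42, matching a median delivery of 40.0 weeks); and the outcome by the
competition rule `pe = (g_pe <= g_other and g_pe <= g_max)`, delivery at
`min(g_pe, g_other)`.

One deliberate design choice: for rows with `g_pe <= g_max`, the (never
observed) counterfactual other-cause time is drawn conditional on
`g_other >= g_pe`.  The scoring model assumes that no other delivery
pre-empts pre-eclampsia inside the risk window; the generator realises
exactly that generative process, so the scored risks are, by construction,
the true conditional probabilities of the generated outcomes.  This is what
makes the end-to-end recovery properties sharp: realised incidence within 3
binomial SE of the summed decimal risks, calibration |alpha| < 0.1 and
|beta - 1| < 0.1 at n = 50,000, and a known 0.5 log-odds miscalibration
offset recovered within 3 SE.

What the generator therefore does *not* emulate: in real cohorts spontaneous
or iatrogenic delivery does pre-empt late pre-eclampsia, so a model of this
family overestimates term PE against real observations (expected counts
~15–30% above observed at term).  Passing recovery tests here demonstrates
that the pipeline is a correct inverse of its own generative assumptions,
not that those assumptions hold in real data.  Accounting for that
censoring in the scorer is explicitly out of scope.  Other simplifications:
covariates are drawn independently apart from weight–height; aspirin use,
stillbirth and neonatal outcomes, analyser-specific PlGF behaviour and
multi-fetal pregnancies are not modelled.  A mis-specification test
documents the diagnostic direction: scoring with the prior sd inflated x1.5
over-disperses predictions and drives the calibration slope below 1.

## Problem sizes and determinism

Default analyses use 50,000-pregnancy cohorts — large enough that binomial
3-SE bands on a ~3% incidence are ±0.23 percentage points, small enough
that a full simulate/score/policy-sweep cycle runs in well under a minute on
one CPU.  Every random draw flows from a single integer seed through
`numpy.random.default_rng`; identical (config, seed) gives bitwise-identical
cohort CSVs.  Unit tests use 500–20,000-row cohorts; Monte-Carlo oracles use
1e5–1e6 draws with 3-SE tolerances.

## Known limitations

* Synthetic coefficients: scenario magnitudes (e.g. subgroup RRR per policy)
  depend on the chosen likelihood slopes and prior spread; only directions
  and identities are asserted, not published effect sizes.
* Term-PE competition bias is absent by design (above).
* The systolic co-reduction model is a stand-in: a deterministic linear
  ratio with a configurable coefficient, not a fitted treatment model.
* Calibration of rare bands (<32 weeks) is noisy below ~10^5 pregnancies.
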