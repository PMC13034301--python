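# pecrisk default configuration, schema v1
#
# SYNTHETIC DEFAULTS.  The coefficient values below are documented synthetic
# choices: they give the bundled cohort generator incidences, blood-pressure
# strata and biomarker spreads on the scale reported for large unselected
# first-trimester screening populations (~0.8% preterm and ~2.1% term
# pre-eclampsia; ~60/21/16/3% ACC/AHA blood-pressure strata).  They are not a
# fit to any study dataset.  Every value can be overridden by passing your
# own copy of this file.
#
# Units: gestational ages in weeks; blood pressure mm Hg; marker regressions
# on the log10 scale; covariate centring noted per term.

risk_model:
  prior:
    # mean gestational age at delivery with pre-eclampsia for the reference
    # woman (white, parous without prior pre-eclampsia, no medical history,
    # weight 69 kg, height 164 cm, age <= 35)
    intercept: 62.34
    sd: 9.59
    effects:
      weight: {per_unit: -0.085, center: 69.0}        # heavier -> earlier PE
      height: {per_unit: 0.055, center: 164.0}
      age: {per_unit: -0.20, hinge: 35.0}             # only above 35 years
      interpregnancy_interval: {per_unit: -0.25, center: 2.9}
      ethnic_group: {black: -2.4, south_asian: -1.0, east_asian: -0.3, mixed: -0.9}
      parity: {nulliparous: -1.1, parous_prior_pe: -5.3}
      smoker: 0.8                                     # smoking lowers PE risk
      family_history_pe: -1.4
      conception: {assisted: -1.7}
      chronic_hypertension: -8.5
      diabetes: {type1: -3.6, type2: -2.7}
      sle_aps: -4.4

  markers:
    map:
      # expected log10 MAP (mm Hg); 1.92942 = log10(85)
      intercept_log10: 1.92942
      regression:
        weight: {per_unit: 0.0012, center: 69.0}
        age: {per_unit: 0.0002, hinge: 35.0}
        ethnic_group: {black: 0.004}
        chronic_hypertension: 0.03
        smoker: -0.004
      slope: -0.004        # log10 MoM per week below the changepoint
      changepoint: 40.0
    uta_pi:
      # expected log10 mean uterine artery PI; 0.21748 = log10(1.65)
      intercept_log10: 0.21748
      regression:
        ga_screening: {per_unit: -0.025, center: 12.7}   # PI falls with gestation
        weight: {per_unit: -0.0015, center: 69.0}
        ethnic_group: {black: 0.01}
      slope: -0.025
      changepoint: 40.0
    plgf:
      # expected log10 PlGF (pg/mL); 1.57978 = log10(38)
      intercept_log10: 1.57978
      regression:
        ga_screening: {per_unit: 0.06, center: 12.7}     # PlGF rises with gestation
        weight: {per_unit: -0.002, center: 69.0}
        ethnic_group: {black: 0.06}
        smoker: 0.07
      slope: 0.030
      changepoint: 40.0

  residual:
    # sd / correlations of log10 MoM residuals (marker order map, uta_pi, plgf)
    sd: {map: 0.030, uta_pi: 0.12, plgf: 0.18}
    corr: {map__uta_pi: 0.06, map__plgf: -0.05, uta_pi__plgf: -0.25}

  grid:
    min: 24.0
    max: 42.0       # latest gestation at which pre-eclampsia can still occur
    step: 0.025
    band_cuts: [32.0, 34.0, 37.0]

generator:
  n: 50000
  seed: 20260922
  covariates:
    age: {mean: 31.1, sd: 5.9, min: 16.0, max: 52.0}
    height: {mean: 164.0, sd: 6.5}
    bmi: {median: 24.7, sigma_log: 0.217}
    weight_height_corr: 0.4
    ethnic_group: {white: 0.7232, black: 0.1734, south_asian: 0.0553, east_asian: 0.0224, mixed: 0.0257}
    smoker: 0.0846
    family_history_pe: 0.0444
    conception_assisted: 0.0347
    parity: {nulliparous: 0.4712, parous_no_pe: 0.4978, parous_prior_pe: 0.0310}
    interpregnancy_interval: {median: 2.9, sigma_log: 0.75}
    chronic_hypertension: 0.0134
    diabetes: {none: 0.9914, type1: 0.0036, type2: 0.0050}
    sle_aps: 0.0019
    ga_screening: {mean: 12.7, sd: 0.59, min: 11.0, max: 14.2}
  bp_model:
    # sbp = intercept + slope * MAP + Normal(0, noise_sd); dbp closes the MAP identity
    sbp_intercept: 30.0
    sbp_slope: 1.0
    sbp_noise_sd: 8.0
  other_cause:
    mean: 40.0
    sd: 1.4
    min: 24.0
    max: 42.0
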