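# Default parameter set for the two-arm Hodgkin-lymphoma cost-effectiveness
# model: experimental brentuximab vedotin + AVD vs standard ABVD.
#
# Scalar values are the published point estimates (costs in 2018 CAD).
# Standard errors are omitted here and therefore resolved by the package
# defaults: binomial SE at the trial per-arm size (n = 664) for
# probabilities, 20% of the mean for costs and utilities. Add an `se:` key
# next to any `mean:` to override.
#
# The Weibull blocks parameterize the time-dependent transitions,
# S(t) = exp(-(t/scale)^shape) with t in months. The source fits were never
# published; these values are calibrated so that the model reproduces the
# clinical regime described in the literature: early-weighted relapse from
# remission (~33% by 15 years on ABVD, hazard ratio ~0.87 for BREN+AVD),
# low remission mortality (~9% over 15 years), frequent post-transplant
# relapse, and salvage-phase survival with a median around 3.5 years. The
# base case consequently has BREN+AVD more costly and slightly more
# effective. var_log_shape / var_log_scale / cov give the covariance of
# (log shape, log scale) used by the probabilistic analysis.
schema_version: 1
model:
  cycle_length_months: 6
  horizon_years: 15
  discount_rate: 0.015
  half_cycle_correction: false
  discount_timing: start
shared:
  probabilities:
    asct_eligible: {mean: 0.8}
    asct_success: {mean: 0.5}
  costs:
    pet_scan: {mean: 1877}
    adverse_event: {mean: 12036}
    asct: {mean: 67723}
    salvage: {mean: 140800}
  utilities:
    treatment: {mean: 0.71}
    complete_remission: {mean: 0.91}
    adverse_event: {mean: 0.59}
    progressive_disease: {mean: 0.38}
arms:
  abvd:
    probabilities:
      serious_adverse_event: {mean: 0.270}
      treatment_discontinuation: {mean: 0.159}
      mortality_on_treatment: {mean: 0.019}
    costs:
      regimen: {mean: 12701}
    weibull:
      progression_cr:
        {shape: 0.75, scale: 600.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_cr:
        {shape: 1.10, scale: 1500.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_progression:
        {shape: 1.00, scale: 120.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      progression_post_asct:
        {shape: 0.80, scale: 200.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_second_progression:
        {shape: 1.00, scale: 60.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
  bren_avd:
    probabilities:
      serious_adverse_event: {mean: 0.429}
      treatment_discontinuation: {mean: 0.133}
      mortality_on_treatment: {mean: 0.013}
    costs:
      regimen: {mean: 116160}
    weibull:
      progression_cr:
        {shape: 0.75, scale: 720.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_cr:
        {shape: 1.10, scale: 1500.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_progression:
        {shape: 1.00, scale: 120.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      progression_post_asct:
        {shape: 0.80, scale: 200.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
      mortality_second_progression:
        {shape: 1.00, scale: 60.0, var_log_shape: 0.0025, var_log_scale: 0.01, cov: -0.002}
run:
  iterations: 10000
  seed: 0
  wtp_grid: {start: 0, stop: 500000, step: 10000}
  price_fractions: [0.0, 0.25, 0.5, 0.75]
  strict_psa: true
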