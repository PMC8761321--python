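# discovery_like: urban community survey of older adults (ages >= 60)
sex_male_frac: 0.4647
age_min: 60.0
age_gamma_shape: 1.6
age_gamma_scale: 5.7
age_center: 69.0
bmi_mean: 24.2
bmi_sd: 2.9
ever_prev_male: 0.20
ever_prev_female: 0.011
current_frac: 0.94
intensity_log_mu: 2.708
intensity_log_sigma: 0.60
intensity_age_per10: -0.10
start_age_mean: 21.0
start_age_sd: 4.0
tsc_gamma_shape: 1.5
tsc_gamma_scale: 6.0
covariates:
  diet: {balanced: 0.9857, vegetarian: 0.0084, meat_based: 0.0059}
  exercise: {never: 0.391, occasional: 0.0147, often: 0.0728, every_day: 0.5215}
  alcohol: {never: 0.9233, occasional: 0.0222, often: 0.0021, every_day: 0.0474, former: 0.0048}
true_effects:
  # per-component log-odds effects, ordered obesity, glucose,
  # blood_pressure, triglycerides, hdl
  csi: [0.031, 0.080, 0.276, 0.013, 0.190]   # per CSI unit at ages >= 70
  age_per10: [0.05, 0.30, 0.35, 0.00, 0.05]
  male: [0.10, 0.00, 0.10, 0.30, -0.30]
  bmi: [0.55, 0.10, 0.12, 0.12, 0.08]
age_modification: 2.4
component_correlation: 0.9
component_base_rates: [0.228, 0.330, 0.429, 0.334, 0.280]
target_mets_prevalence: 0.233
missingness_rate: 0.071
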