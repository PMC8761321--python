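# replication_like: nationwide multi-province adult survey (ages >= 18)
sex_male_frac: 0.4642
age_min: 18.0
age_gamma_shape: 4.55
age_gamma_scale: 7.03
age_center: 50.0
bmi_mean: 23.4
bmi_sd: 3.2
ever_prev_male: 0.58
ever_prev_female: 0.05
current_frac: 0.928
intensity_log_mu: 2.77
intensity_log_sigma: 0.75
intensity_age_per10: -0.30
start_age_mean: 20.0
start_age_sd: 4.0
tsc_gamma_shape: 1.5
tsc_gamma_scale: 6.0
covariates:
  alcohol: {never: 0.677, occasional: 0.114, often: 0.115, every_day: 0.094}
  region: {rural: 0.6707, urban: 0.3293}
  province:
    liaoning: 0.0950
    heilongjiang: 0.1026
    jiangsu: 0.1306
    shandong: 0.1113
    henan: 0.1136
    hubei: 0.1064
    hunan: 0.1266
    guangxi: 0.1235
    guizhou: 0.0905
  sports_like:
    does_not_participate: 0.0578
    dislike_very_much: 0.0373
    dislike_somewhat: 0.6005
    neutral: 0.2008
    like_somewhat: 0.0961
    like_very_much: 0.0076
true_effects:
  # per-component log-odds effects, ordered obesity, glucose,
  # blood_pressure, triglycerides, hdl
  csi: [0.000, 0.030, 0.050, 0.050, 0.120]   # per CSI unit at ages >= 70
  age_per10: [0.35, 0.45, 0.45, 0.15, 0.10]
  male: [0.10, 0.00, 0.10, 0.30, -0.30]
  bmi: [0.60, 0.10, 0.12, 0.12, 0.08]
age_modification: 2.4
component_correlation: 0.9
component_base_rates: [0.330, 0.135, 0.424, 0.307, 0.131]
target_mets_prevalence: 0.182
missingness_rate: 0.071
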