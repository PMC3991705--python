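n_per_arm:
- 369
- 366
arm_labels:
- intervention
- control
resource_models:
  inpatient_days:
    dist: lognormal_halfday
    intervention:
      mean: 12.55
      sd: 15.46
    control:
      mean: 11.56
      sd: 11.68
  itu_days:
    dist: zinb
    zero_prob: 0.8
    intervention:
      mean: 0.93
      sd: 3.12
    control:
      mean: 1.06
      sd: 5.46
  hdu_days:
    dist: zinb
    zero_prob: 0.6
    intervention:
      mean: 0.6
      sd: 1.67
    control:
      mean: 0.51
      sd: 1.03
  gp_visits:
    dist: zinb
    zero_prob: 0.5
    intervention:
      mean: 0.43
      sd: 0.81
    control:
      mean: 0.51
      sd: 1.03
  practice_nurse_visits:
    dist: zinb
    zero_prob: 0.85
    intervention:
      mean: 0.16
      sd: 0.7
    control:
      mean: 0.32
      sd: 1.21
  district_nurse_visits:
    dist: zinb
    zero_prob: 0.7
    intervention:
      mean: 3.43
      sd: 7.24
    control:
      mean: 3.52
      sd: 6.94
  outpatient_visits:
    dist: zinb
    zero_prob: 0.6
    intervention:
      mean: 0.42
      sd: 1.09
    control:
      mean: 0.31
      sd: 0.71
  medication_cost:
    dist: gamma
    intervention:
      mean: 1.0
      sd: 3.84
    control:
      mean: 1.0
      sd: 5.74
utility_model:
  latent_corr: 0.5
  intervention:
    baseline:
    - 0.751
    - 0.307
    mid:
    - 0.6
    - 0.3
    day30:
    - 0.683
    - 0.307
  control:
    baseline:
    - 0.752
    - 0.306
    mid:
    - 0.6
    - 0.3
    day30:
    - 0.684
    - 0.306
cost_calibration:
  intervention:
    cost_mean: 5420.0
    cost_se: 246.0
    qaly_mean: 0.02131
    qaly_se: 0.0014
  control:
    cost_mean: 5130.0
    cost_se: 234.0
    qaly_mean: 0.02133
    qaly_se: 0.0014
missingness:
  inpatient_days:
    intervention: 0.02710027100271003
    control: 0.02185792349726776
    mechanism: MCAR
  gp_visits:
    intervention: 0.013550135501355014
    control: 0.02185792349726776
    mechanism: MCAR
  practice_nurse_visits:
    intervention: 0.008130081300813009
    control: 0.01366120218579235
    mechanism: MCAR
  district_nurse_visits:
    intervention: 0.024390243902439025
    control: 0.030054644808743168
    mechanism: MCAR
  outpatient_visits:
    intervention: 0.013550135501355014
    control: 0.00819672131147541
    mechanism: MCAR
  eq5d_30d:
    intervention: 0.13821138211382114
    control: 0.1448087431693989
    mechanism: MCAR
  eq5d_baseline:
    intervention: 0.03
    control: 0.03
    mechanism: MCAR
  eq5d_mid:
    intervention: 0.08
    control: 0.08
    mechanism: MCAR
  bmi:
    intervention: 0.02
    control: 0.02
    mechanism: MCAR
  diabetes:
    intervention: 0.01
    control: 0.01
    mechanism: MCAR
  smoker:
    intervention: 0.01
    control: 0.01
    mechanism: MCAR
mortality_rate:
  intervention: 0.02168021680216802
  control: 0.03278688524590164
covariate_model:
  age_mean: 62.0
  age_sd: 14.0
  age_range:
  - 18.0
  - 95.0
  bmi_mean: 27.5
  bmi_sd: 5.0
  bmi_range:
  - 15.0
  - 50.0
  diabetes: 0.12
  smoker: 0.2
  emergency_surgery: 0.25
  stoma_planned: 0.35
  viscus_planned: 0.75
  ssi_control: 0.253
  ssi_odds_ratio: 0.97
seed: 0
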