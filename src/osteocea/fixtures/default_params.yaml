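adherence: 0.9
ai_duration_years: 5
background_mortality:
  '100': 0.342723
  '101': 0.378011
  '60': 0.0068
  '61': 0.0075
  '62': 0.008272
  '63': 0.009124
  '64': 0.010064
  '65': 0.0111
  '66': 0.012243
  '67': 0.013503
  '68': 0.014893
  '69': 0.016427
  '70': 0.018118
  '71': 0.019984
  '72': 0.022041
  '73': 0.024311
  '74': 0.026814
  '75': 0.029575
  '76': 0.03262
  '77': 0.035979
  '78': 0.039683
  '79': 0.043769
  '80': 0.048275
  '81': 0.053246
  '82': 0.058728
  '83': 0.064775
  '84': 0.071445
  '85': 0.078801
  '86': 0.086914
  '87': 0.095863
  '88': 0.105734
  '89': 0.11662
  '90': 0.128628
  '91': 0.141872
  '92': 0.156479
  '93': 0.172591
  '94': 0.190361
  '95': 0.209961
  '96': 0.231579
  '97': 0.255423
  '98': 0.281723
  '99': 0.310729
bmd_baseline:
  '60': -1.2
  '65': -1.5
  '70': -1.8
  '75': -2.1
bmd_baseline_sd: 1.0
bmd_loss_natural:
  '60': 0.036
  '70': 0.045
  '80': 0.05
bmd_loss_on_ai: 0.13
cancer_transition_fits:
  crs_to_dm:
    distribution: lognormal
    params:
      mu: 2.6
      sigma: 1.3
  dfs_to_crs:
    distribution: lognormal
    params:
      mu: 5.0
      sigma: 1.5
  dfs_to_lrs:
    distribution: lognormal
    params:
      mu: 4.0
      sigma: 1.4
  dm_to_death:
    distribution: lognormal
    params:
      mu: 1.55
      sigma: 0.9
  lrs_to_dm:
    distribution: lognormal
    params:
      mu: 2.2
      sigma: 1.2
costs:
  drug_annual:
    alendronate: 65.0
    denosumab: 440.0
    zoledronate: 75.0
  dxa: 26.2
  fracture_acute:
    hip: 4900.0
    other: 1500.0
    vertebral: 2600.0
  fracture_annual:
    hip: 390.0
    other: 60.0
    vertebral: 150.0
  indirect_bedridden_annual: 1560.0
  indirect_post_fracture_first_year: 720.0
  long_term_care_annual: 3100.0
discount_rate: 0.05
dm_mortality_hr: 1.0
fracture_gradient:
  hip: 2.6
  other: 1.5
  vertebral: 1.8
fracture_rate_curves:
  hip:
    a: 0.00089
    b: 0.1
    ref_age: 60
  other:
    a: 0.0037
    b: 0.025
    ref_age: 60
  vertebral:
    a: 0.00444
    b: 0.045
    ref_age: 60
hip_fracture_mortality_hr:
  '60': 2.8
  '70': 2.4
  '80': 2.0
  '90': 1.6
initial_prior_fracture: false
max_age: 100
p_bedridden_after_hip: 0.1
perspective: healthcare
psa_distributions:
  adherence:
    args:
      alpha: 36.0
      beta: 4.0
    family: beta
  bmd_loss_on_ai:
    args:
      scale: 0.0052
      shape: 25.0
    family: gamma
  costs.drug_annual.alendronate:
    args:
      scale: 2.6
      shape: 25.0
    family: gamma
  costs.dxa:
    args:
      scale: 1.048
      shape: 25.0
    family: gamma
  costs.fracture_acute.hip:
    args:
      scale: 196.0
      shape: 25.0
    family: gamma
  costs.fracture_acute.other:
    args:
      scale: 60.0
      shape: 25.0
    family: gamma
  costs.fracture_acute.vertebral:
    args:
      scale: 104.0
      shape: 25.0
    family: gamma
  costs.long_term_care_annual:
    args:
      scale: 124.0
      shape: 25.0
    family: gamma
  fracture_rate_curves.hip.a:
    args:
      scale: 3.56e-05
      shape: 25.0
    family: gamma
  fracture_rate_curves.other.a:
    args:
      scale: 0.00014800000000000002
      shape: 25.0
    family: gamma
  fracture_rate_curves.vertebral.a:
    args:
      scale: 0.0001776
      shape: 25.0
    family: gamma
  p_bedridden_after_hip:
    args:
      alpha: 10.0
      beta: 90.0
    family: beta
  rr_subsequent_fracture.hip:
    args:
      mu: 0.6931471805599453
      sigma: 0.15
    family: lognormal
  rr_subsequent_fracture.other:
    args:
      mu: 0.5877866649021191
      sigma: 0.15
    family: lognormal
  treatment_rr.alendronate.hip:
    args:
      mu: -0.5108256237659907
      sigma: 0.12
    family: lognormal
  treatment_rr.alendronate.other:
    args:
      mu: -0.21072103131565253
      sigma: 0.1
    family: lognormal
  treatment_rr.alendronate.vertebral:
    args:
      mu: -0.5978370007556204
      sigma: 0.12
    family: lognormal
  utilities.bedridden:
    args:
      alpha: 14.0
      beta: 36.0
    family: beta
  utilities.fracture_first_year.hip:
    args:
      alpha: 42.0
      beta: 18.0
    family: beta
  utilities.fracture_first_year.other:
    args:
      alpha: 54.6
      beta: 5.4
    family: beta
  utilities.fracture_first_year.vertebral:
    args:
      alpha: 49.2
      beta: 10.8
    family: beta
residual_duration_years:
  alendronate: 5.0
  denosumab: 0.0
  zoledronate: 3.0
risk_modifiers:
  prior_falls_rr: 1.6
  prior_fracture_rr: 1.8
rr_subsequent_fracture:
  hip: 2.0
  other: 1.8
  vertebral: 1.0
start_age: 60
treatment_duration_years:
  alendronate: 5.0
  denosumab: 5.0
  zoledronate: 3.0
treatment_rr:
  alendronate:
    hip: 0.6
    other: 0.81
    vertebral: 0.55
  denosumab:
    hip: 0.6
    other: 0.8
    vertebral: 0.32
  zoledronate:
    hip: 0.59
    other: 0.75
    vertebral: 0.3
utilities:
  baseline:
    '60': 0.91
    '70': 0.87
    '80': 0.81
    '90': 0.75
  bedridden: 0.28
  cancer_state:
    contralateral_recurrence: 0.85
    disease_free: 0.94
    distant_metastasis: 0.65
    locoregional_recurrence: 0.85
  fracture_first_year:
    hip: 0.7
    other: 0.91
    vertebral: 0.82
  fracture_subsequent:
    hip: 0.9
    other: 1.0
    vertebral: 0.93
wtp: 38223.0
wtp_high: 50964.0
zscore_reference:
  age_mean:
    '100': 0.508
    '101': 0.5025
    '60': 0.728
    '61': 0.7225
    '62': 0.717
    '63': 0.7115
    '64': 0.706
    '65': 0.7005
    '66': 0.695
    '67': 0.6895
    '68': 0.684
    '69': 0.6785
    '70': 0.673
    '71': 0.6675
    '72': 0.662
    '73': 0.6565
    '74': 0.651
    '75': 0.6455
    '76': 0.64
    '77': 0.6345
    '78': 0.629
    '79': 0.6235
    '80': 0.618
    '81': 0.6125
    '82': 0.607
    '83': 0.6015
    '84': 0.596
    '85': 0.5905
    '86': 0.585
    '87': 0.5795
    '88': 0.574
    '89': 0.5685
    '90': 0.563
    '91': 0.5575
    '92': 0.552
    '93': 0.5465
    '94': 0.541
    '95': 0.5355
    '96': 0.53
    '97': 0.5245
    '98': 0.519
    '99': 0.5135
  age_sd:
    '100': 0.11
    '101': 0.11
    '60': 0.11
    '61': 0.11
    '62': 0.11
    '63': 0.11
    '64': 0.11
    '65': 0.11
    '66': 0.11
    '67': 0.11
    '68': 0.11
    '69': 0.11
    '70': 0.11
    '71': 0.11
    '72': 0.11
    '73': 0.11
    '74': 0.11
    '75': 0.11
    '76': 0.11
    '77': 0.11
    '78': 0.11
    '79': 0.11
    '80': 0.11
    '81': 0.11
    '82': 0.11
    '83': 0.11
    '84': 0.11
    '85': 0.11
    '86': 0.11
    '87': 0.11
    '88': 0.11
    '89': 0.11
    '90': 0.11
    '91': 0.11
    '92': 0.11
    '93': 0.11
    '94': 0.11
    '95': 0.11
    '96': 0.11
    '97': 0.11
    '98': 0.11
    '99': 0.11
  young_adult_mean: 0.86
  young_adult_sd: 0.11
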