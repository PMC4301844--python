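# Base-case inputs: adjuvant chemotherapy after D2 gastrectomy for
# stage II/III gastric cancer, Chinese healthcare-system perspective,
# 2013 USD.  Surgery-only survival is a two-piece Weibull model
# (cumulative hazard H(t) = scale * t^shape, t in weeks, pieces anchored
# at the origin); adjuvant strategies apply indirect-comparison hazard
# ratios to it.

reference: surgery
intervention: xelox

survival_models:
  rfs:
    - {scale: 0.001554, shape: 1.202, t_start: 0, t_end: 97}
    - {scale: 0.02754, shape: 0.5736, t_start: 97, t_end: null}
  os:
    - {scale: 0.00005097, shape: 1.755, t_start: 0, t_end: 141}
    - {scale: 0.005259, shape: 0.8171, t_start: 141, t_end: null}

strategies:
  - name: surgery
    hr_rfs: 1.0
    hr_os: 1.0
    regimen: none
  - name: s1
    hr_rfs: {point: 0.653, ci_low: 0.537, ci_high: 0.793}
    hr_os: {point: 0.669, ci_low: 0.540, ci_high: 0.828}
    regimen: s1
  - name: xelox
    hr_rfs: {point: 0.58, ci_low: 0.47, ci_high: 0.72}
    hr_os: {point: 0.66, ci_low: 0.51, ci_high: 0.85}
    regimen: xelox

costs:  # 2013 USD; ranges read as 95% intervals
  capecitabine_per_500mg: 6.6          # fixed
  s1_per_20mg: {median: 9.6, low: 7.9, high: 10.1}
  oxaliplatin_per_50mg: {median: 88.9, low: 77.3, high: 464.5}
  followup_per_unit: {median: 56.5, low: 42.3, high: 70.6}
  tests_s1_per_6wk: {median: 197.8, low: 15.9, high: 317.5}
  salvage_per_3wk: {median: 2334.6, low: 1429.3, high: 3323.2}
  end_of_life: {median: 1460.3, low: 1055.3, high: 2085.7}
  supportive_per_cycle: {median: 115.2, low: 31.7, high: 317.5}
  adr_s1_per_6wk: {median: 42.3, low: 7.9, high: 79.4}
  adr_xelox_per_3wk: {median: 68.9, low: 15.9, high: 158.7}
  hosp_xelox_per_3wk: {median: 373.0, low: 238.1, high: 793.7}

utilities:
  u_rfs: 0.88
  u_rec: 0.42
  u_rfs_range: [0.80, 0.97]
  u_rec_range: [0.28, 0.63]

patient:
  weight_kg: 65
  height_m: 1.64
  bsa: 1.72

settings:
  discount_rate: 0.03
  start_age: 59.5
  horizon_age: 100
  wtp_1x: 6100
  wtp_3x: 18300
  half_cycle_correction: false

background_mortality:
  mode: additive   # max | additive | off
  from_week: 260   # trial follow-up horizon (5 years); natural-cause
                   # mortality is added to the disease model beyond it
  life_table: null # null -> bundled synthetic table

costing:
  death_attribution: excess      # excess | all
  followup_interval_weeks: 12
  s1_rounding: nearest           # oral dose banding; "up" bills every opened unit
  capecitabine_rounding: nearest
  recurrence_care:
    salvage_fraction: 0.865
    supportive_fraction: 0.135
    salvage_cycles: 7

sensitivity:
  psa_iterations: 1000
  seed: 20130101
  wtp_grid: {start: 0, stop: 20000, step: 500}
  discount_range: [0.0, 0.06]
  followup_interval_range: [6, 26]

# Published model-outcome survival (percent) used by the validation
# report; trial_pct is the corresponding trial estimate.
validation:
  - {strategy: surgery, endpoint: RFS, years: 3, expected_pct: 60.8, trial_pct: 59.6}
  - {strategy: s1,      endpoint: RFS, years: 3, expected_pct: 72.3, trial_pct: 72.2}
  - {strategy: xelox,   endpoint: RFS, years: 3, expected_pct: 75.0, trial_pct: 74.0}
  - {strategy: surgery, endpoint: RFS, years: 5, expected_pct: 51.2, trial_pct: 53.1}
  - {strategy: s1,      endpoint: RFS, years: 5, expected_pct: 64.6, trial_pct: 65.4}
  - {strategy: xelox,   endpoint: RFS, years: 5, expected_pct: 67.9, trial_pct: 68.0}
  - {strategy: surgery, endpoint: OS,  years: 3, expected_pct: 72.2, trial_pct: 70.1}
  - {strategy: s1,      endpoint: OS,  years: 3, expected_pct: 80.4, trial_pct: 80.1}
  - {strategy: xelox,   endpoint: OS,  years: 3, expected_pct: 80.7, trial_pct: 83.0}
  - {strategy: surgery, endpoint: OS,  years: 5, expected_pct: 60.9, trial_pct: 61.1}
  - {strategy: s1,      endpoint: OS,  years: 5, expected_pct: 71.8, trial_pct: 71.7}
  - {strategy: xelox,   endpoint: OS,  years: 5, expected_pct: 72.1, trial_pct: 78.0}
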