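# Example configuration for the lifehorizon CLI.
#
# The cohort section mirrors the code sets a real claims analysis would
# supply (imaging procedures, comorbidity ICD-10 prefixes, severity-score
# predictors).  The values shipped here are the synthetic placeholders used
# by the generator; substitute national code lists for real data.

cohort:
  imaging_codes: [CT01, MRI01]
  imaging_window_days: [7, 30]      # days before/after the index date
  min_age: 18
  comorbidity_codes:
    AF: [I48]
    CHF: [I50]
    CKD: [N18]
    COPD: [J44]
    diabetes: [E10, E11, E12, E13, E14]
    hyperlipidemia: [E78]
    hypertension: [I10, I11, I12, I13, I15]
    IHD: [I20, I21, I22, I23, I24, I25]
    TIA: [G45]
  ssi:
    intercept: 4.1
    score_min: 4.1
    score_max: 27.11
    coefficients:        # first-stay service-use indicators -> weight
      ICU: 4.0
      AIRWAY: 3.0
      NGTUBE: 2.5
      FOLEY: 2.0
      REHAB: 1.5

life_table:
  first_year: 2002
  last_year: 2015
  max_age: 110

scenario:                 # synthetic-cohort generation (simulate / run-all)
  n_patients: 2000
  washout_noise_rate: 0.05
  nonhosp_rate: 0.08
  no_imaging_rate: 0.03
  index_end: "2006-12-31"

estimation:
  n_replicates: 100       # Monte-Carlo referent lifetimes per patient
  rolling_window: 36      # months of trailing W history per OLS step
  bootstrap_B: 0          # >= 2 enables bootstrap SEs

costs:
  discount_rates: [0.0, 0.03, 0.05]
  krw_per_usd: 1131.2     # 2015 average exchange rate

risk:
  sampling_fraction: 0.02 # national sample fraction per calendar year
  base_population: 50000

validation:
  fit_months: 60
  test_months: 120
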