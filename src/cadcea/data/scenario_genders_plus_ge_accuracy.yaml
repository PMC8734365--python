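## The `genders_us` setting with only the imaging accuracy (CMR and CCTA
## sensitivity/specificity) replaced by the more recent estimates of the
## `ge_us` case; test costs and everything else stay at `genders_us` values.
name: genders_plus_ge_accuracy
currency: USD
prevalence: 0.3
age: 60.0
male_fraction: 0.53
test_profiles:
  cmr: {sensitivity: 0.89, specificity: 0.87, cost: 621.0}
  ccta: {sensitivity: 0.90, specificity: 0.71, cost: 372.0}
  spect: {sensitivity: 0.70, specificity: 0.75, cost: 550.0}
ica_cost: 2989.0
cabg_cost: 38217.0
pci_cost: 6529.0
medical_therapy_annual_cost: 1200.0
revascularization_fraction: 0.6
cabg_share: 0.3
utility_no_mace: 0.84
utility_mace: 0.78
mace_first_year_cost: 14500.0
mace_subsequent_annual_cost: 3400.0
discount_rate: 0.03
wtp: 100000.0
fn_return_prob: 0.58
horizon_age: 100.0
cohort_params:
  annual_first_mace_prob_treated_cad: 0.025
  annual_first_mace_prob_untreated_cad: 0.06
  annual_first_mace_prob_no_cad: 0.006
  recurrent_mace_multiplier: 2.0
  mace_case_fatality: 0.15
  background_mortality:
    40.0: 0.002
    45.0: 0.003
    50.0: 0.0043
    55.0: 0.0062
    60.0: 0.0092
    65.0: 0.0133
    70.0: 0.0203
    75.0: 0.031
    80.0: 0.0512
    85.0: 0.0855
    90.0: 0.139
    95.0: 0.216
    100.0: 0.313
    105.0: 0.4
sources:
  prevalence: published
  age: published
  male_fraction: default
  test_profiles.cmr: published accuracy, genders_us cost
  test_profiles.ccta: published accuracy, genders_us cost
  test_profiles.spect: default
  ica_cost: published
  cabg_cost: published
  pci_cost: published
  medical_therapy_annual_cost: default
  revascularization_fraction: default
  cabg_share: default
  utility_no_mace: published
  utility_mace: published
  mace_first_year_cost: default
  mace_subsequent_annual_cost: published
  discount_rate: published
  wtp: published
  fn_return_prob: published
  horizon_age: default
  cohort_params: default
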