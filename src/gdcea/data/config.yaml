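# Run configuration for the Gaucher disease ERT cost-effectiveness model.
# Lifetime horizon from birth, one-year cycles, Dutch discounting convention
# (effects 1.5%/yr, costs 4%/yr), PSA design of 1,000 second-order draws with
# 100 first-order trials each.
horizon_years: 85
cycle_years: 1.0
discount_effects: 0.015
discount_costs: 0.04
productive_age_window: [25, 64]
wtp_grid: {start: 0, stop: 10000000, step: 10000}
psa_draws: 1000
psa_trials: 100
seed: 2014
tariff: UK

ert_vial_unit_cost: 1985.0

files:
  transitions: transitions_synthetic.csv
  utilities: utilities.csv
  costs: costs.csv
  ert_dosing: ert_dosing.csv
  start_distribution: start_distribution.csv
  life_table: life_table_synthetic.csv

strategies:
  no_ert:
    malignancy_excess_mortality: 0.15
  ert_base:
    malignancy_excess_mortality: 0.15
  ert_historical:
    malignancy_excess_mortality: 0.15

# Synthetic placeholder 1991 cohort distributions for the historical
# scenarios (the source distributions are not publicly printed).
scenario_start_distributions:
  historical_I:
    signs_symptoms: 0.40
    splenectomy: 0.20
    bone_complication: 0.15
    multiple_complications: 0.20
    malignancy: 0.05
  historical_II:
    signs_symptoms: 0.15
    splenectomy: 0.25
    bone_complication: 0.15
    multiple_complications: 0.35
    malignancy: 0.10
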