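# Built-in base-case inputs for the CRT-D battery-longevity cost model.
# All monetary amounts are 2023 USD. Survival tables are printed as percents
# (percent: true) and converted to fractions on load.
schema_version: 1

settings:
  horizon_years: 6
  discount_rate: 0.03
  max_replacements: 3
  complication_lag_years: 0

population:
  annual_implants: 15577
  cohort_entry_years: 7

patient_survival:
  percent: true
  values: [100, 95, 90, 85, 81, 77, 72]

devices:
  - label: "2.1 Ah"
    capacity_ah: 2.1
    battery_survival:
      percent: true
      values: [100, 100, 98, 98, 95, 90, 77]
  - label: "1.0 Ah"
    capacity_ah: 1.0
    battery_survival:
      percent: true
      values: [100, 100, 99, 92, 74, 36, 10]
  - label: "1.6 Ah"
    capacity_ah: 1.6
    battery_survival:
      percent: true
      values: [100, 100, 100, 100, 90, 69, 44]

complications:
  percent: true
  complication_primary: 4
  complication_replacement: 2
  infection_primary: 2
  infection_replacement: 3
  cost_complication: 1112
  cost_infection: 29550

costs:
  initial_implant: 34436
  replacement: 32123
  followup_visit: 82
  routine_visits_per_year: 4
  postprocedure_visits: 1
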