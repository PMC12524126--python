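# Base case: neurofeedback + other therapy (intervention) vs pharmacotherapy.
name: nf_vs_pharmacotherapy
strategies:
- name: nf_ot
  per_session_cost: 140.0
  sessions_per_course: 13.5
  per_course_cost: 1890.0
  annual_drug_cost: 0.0
  course_cycles: 1
  dropout_course_prob: 0.132
  relapse_prob: 0.14
  relapse_cycles: 1
  retreatment_prob: 0.5
  effect_mean: 7.01
  effect_dispersion: 11.3   # 95% CI 1.36 to 12.66
  effect_dispersion_kind: ci95
- name: pharmacotherapy
  per_session_cost: 0.0
  sessions_per_course: 0.0
  per_course_cost: 0.0
  annual_drug_cost: 1415.0
  course_cycles: 1
  dropout_course_prob: 0.33
  relapse_prob: 0.174
  relapse_cycles: 1
  retreatment_prob: 0.5
  effect_mean: 6.64
  effect_dispersion: 4.95   # 95% CI 4.16 to 9.11
  effect_dispersion_kind: ci95
bands:
- {label: severe, caps5_low: 60, caps5_high: 80}
- {label: moderate, caps5_low: 40, caps5_high: 59}
- {label: mild, caps5_low: 20, caps5_high: 39}
- {label: asymptomatic, caps5_low: 0, caps5_high: 19}
state_costs:
  quarterly_cost_by_band:
    severe: 5880.0
    moderate: 4900.0
    mild: 3450.0
    asymptomatic: 0.0
mortality:
  quarterly_death_prob_by_band:
    severe: 0.001
    moderate: 0.0008
    mild: 0.00065
    asymptomatic: 0.0005
initial_distribution:
  severe: 0.333333333333334
  moderate: 0.333333333333333
  mild: 0.333333333333333
horizon_cycles: 12
cycle_length_years: 0.25
annual_discount_rate: 0.03
wtp_per_qaly: 0.0
regression:
  intercept: 92.0
  slope: -0.68
psa_distributions:
  strategies.nf_ot.dropout_course_prob: {family: beta, derived_from: [0.132, 0.0264]}
  strategies.pharmacotherapy.dropout_course_prob: {family: beta, derived_from: [0.33, 0.066]}
  strategies.nf_ot.relapse_prob: {family: beta, derived_from: [0.14, 0.028]}
  strategies.pharmacotherapy.relapse_prob: {family: beta, derived_from: [0.174, 0.05]}
  strategies.nf_ot.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.pharmacotherapy.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.nf_ot.effect_mean: {family: normal, derived_from: [7.01, 2.882653]}
  strategies.pharmacotherapy.effect_mean: {family: normal, derived_from: [6.64, 1.262755]}
  strategies.nf_ot.per_course_cost: {family: gamma, derived_from: [1890.0, 378.0]}
  strategies.pharmacotherapy.annual_drug_cost: {family: gamma, derived_from: [1415.0, 283.0]}
  state_costs.severe: {family: gamma, derived_from: [5880.0, 1176.0]}
  state_costs.moderate: {family: gamma, derived_from: [4900.0, 980.0]}
  state_costs.mild: {family: gamma, derived_from: [3450.0, 690.0]}
half_cycle: false
therapy_billing: first_course
seed: 20231
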