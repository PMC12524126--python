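# Base case: neurofeedback + other therapy (intervention) vs psychotherapy.
# Costs are 2023 USD; probabilities act per quarterly cycle; effect dispersions
# are either an SD or a full 95% CI width (kind: ci95).
name: nf_vs_psychotherapy
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
- name: psychotherapy
  per_session_cost: 147.0
  sessions_per_course: 13.5
  per_course_cost: 1985.0
  annual_drug_cost: 0.0
  course_cycles: 1
  dropout_course_prob: 0.206   # midpoint of the reported 17.2-24% range
  relapse_prob: 0.14
  relapse_cycles: 1
  retreatment_prob: 0.5
  effect_mean: 6.25   # pooled 5.98 reweighted to the NF group's military/civilian mix
  effect_dispersion: 4.94
  effect_dispersion_kind: sd
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
  strategies.psychotherapy.dropout_course_prob: {family: beta, derived_from: [0.206, 0.017347]}
  strategies.nf_ot.relapse_prob: {family: beta, derived_from: [0.14, 0.028]}
  strategies.psychotherapy.relapse_prob: {family: beta, derived_from: [0.14, 0.028]}
  strategies.nf_ot.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.psychotherapy.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.nf_ot.effect_mean: {family: normal, derived_from: [7.01, 2.882653]}
  strategies.psychotherapy.effect_mean: {family: normal, derived_from: [6.25, 4.94]}
  strategies.nf_ot.per_course_cost: {family: gamma, derived_from: [1890.0, 378.0]}
  strategies.psychotherapy.per_course_cost: {family: gamma, derived_from: [1985.0, 397.0]}
  state_costs.severe: {family: gamma, derived_from: [5880.0, 1176.0]}
  state_costs.moderate: {family: gamma, derived_from: [4900.0, 980.0]}
  state_costs.mild: {family: gamma, derived_from: [3450.0, 690.0]}
half_cycle: false
therapy_billing: first_course
seed: 20230
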