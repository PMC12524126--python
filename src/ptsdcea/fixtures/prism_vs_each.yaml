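# Amygdala-EFP neurofeedback (Prism) adjunct vs psychotherapy and vs
# pharmacotherapy.  strategies[0] is the intervention; comparisons run
# pairwise against each later strategy.
name: prism_vs_each
strategies:
- name: prism_ot
  per_session_cost: 140.0
  sessions_per_course: 13.5
  per_course_cost: 1890.0
  annual_drug_cost: 0.0
  course_cycles: 1
  dropout_course_prob: 0.132
  relapse_prob: 0.14
  relapse_cycles: 1
  retreatment_prob: 0.5
  effect_mean: 13.2
  effect_dispersion: 6.4   # 95% CI 10 to 16.4
  effect_dispersion_kind: ci95
- name: psychotherapy
  per_session_cost: 147.0
  sessions_per_course: 13.5
  per_course_cost: 1985.0
  annual_drug_cost: 0.0
  course_cycles: 1
  dropout_course_prob: 0.206
  relapse_prob: 0.14
  relapse_cycles: 1
  retreatment_prob: 0.5
  effect_mean: 6.25
  effect_dispersion: 4.94
  effect_dispersion_kind: sd
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
  effect_dispersion: 4.95
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
  strategies.prism_ot.dropout_course_prob: {family: beta, derived_from: [0.132, 0.0264]}
  strategies.psychotherapy.dropout_course_prob: {family: beta, derived_from: [0.206, 0.017347]}
  strategies.pharmacotherapy.dropout_course_prob: {family: beta, derived_from: [0.33, 0.066]}
  strategies.prism_ot.effect_mean: {family: normal, derived_from: [13.2, 1.632653]}
  strategies.psychotherapy.effect_mean: {family: normal, derived_from: [6.25, 4.94]}
  strategies.pharmacotherapy.effect_mean: {family: normal, derived_from: [6.64, 1.262755]}
  strategies.prism_ot.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.psychotherapy.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
  strategies.pharmacotherapy.retreatment_prob: {family: beta, derived_from: [0.5, 0.15306]}
half_cycle: false
therapy_billing: first_course
seed: 20232
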