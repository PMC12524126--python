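# ptsdcea

Markov cohort cost-effectiveness modelling of adjunctive neurofeedback
(NF + OT) versus guideline psychotherapy and pharmacotherapy for
post-traumatic stress disorder, for health-economics analysts who want the
model as inspectable, tested code rather than a proprietary decision-tree
project.

## The model

A cohort of PTSD patients moves between health states in quarterly cycles
over three years (12 cycles). Severity is banded on the Clinician-Administered
PTSD Scale (CAPS-5, 0–80, lower is better): severe 60–80, moderate 40–59,
mild 20–39, asymptomatic 0–19. Each cycle the events compose in the order

death → dropout → relapse (with a retreatment split) → improvement,

each conditional on the previous not occurring. Improvement moves at most one
band per cycle with probability

P(cross) = (1/w) ∫₀ʷ P(max(0, N(μ, σ)) > d) dd,

the chance that a patient uniform within a band of width *w* receiving a
Normal(μ, σ) CAPS-5 reduction (censored at 0) falls below the band floor.
Dropped-out patients freeze at the band they dropped out at; relapsing
responders return to their entry band (retreated, probability 0.2–0.8) or
drop out there; asymptomatic is absorbing apart from background death.

Costs (2023 USD: quarterly care costs of 5880/4900/3450 for severe/moderate/
mild plus therapy courses of USD 1985 psychotherapy, USD 1890 NF +
psychotherapy, USD 1415/year pharmacotherapy) and utilities (EQ-VAS/100 via a
linear CAPS-5 → EQ-VAS map) accrue per cycle and are discounted at 3%/year.
Strategies are compared by incremental cost, incremental QALYs and the ICER
ΔC/ΔE, with dominance classification on the cost-effectiveness plane, a
10,000-draw probabilistic sensitivity analysis (gamma costs, beta
probabilities, normal effects), CEAC, tornado diagrams and one-way threshold
solving. A patient-level microsimulation reproduces the cohort engine
draw-by-draw and serves as its brute-force oracle.

## Worked example

```python
import ptsdcea as p

scn = p.load_fixture("nf_vs_psychotherapy")
_, nf = p.run_strategy(scn, "nf_ot")
_, psych = p.run_strategy(scn, "psychotherapy")
for year, (cost_nf, _) in nf.cumulative_by_year().items():
    print(f"year {year}: NF saves {psych.cumulative_by_year()[year][0] - cost_nf:7.0f} USD")
inc = p.compare(nf, psych)
print(f"delta QALY {inc.delta_qaly:+.4f}, classification: {inc.classification}")

psa = p.run_psa(scn, n=10_000, seed=1)
print(f"dominant {psa.fraction_dominant:.1%}, cheaper {psa.fraction_cheaper:.1%}")
```

prints

```
year 1: NF saves     663 USD
year 2: NF saves    2336 USD
year 3: NF saves    4365 USD
delta QALY +0.0612, classification: dominant
dominant 66.7%, cheaper 68.1%
```

The neurofeedback adjunct costs less cumulatively at each year (its lower
dropout rate keeps more patients improving toward the zero-cost asymptomatic
state) and adds about 0.06 discounted QALYs over three years, so it dominates
psychotherapy in the base case; across the PSA draws it is the cheaper
strategy in about two thirds of parameter draws.

The same surface is available from the shell:

```sh
ptsdcea run --scenario src/ptsdcea/fixtures/nf_vs_psychotherapy.yaml \
        --out out/ --psa-n 10000 --seed 1
ptsdcea threshold --scenario src/ptsdcea/fixtures/nf_vs_psychotherapy.yaml \
        --param strategies.psychotherapy.dropout_course_prob --low 0.01 --high 0.5
```

## Layout

- `src/ptsdcea/scenario.py` — validated model specification, YAML round-trip,
  method-of-moments distribution fitting, shipped base-case fixtures
- `src/ptsdcea/engine.py` — transition matrices, cohort traces, discounted
  cost/QALY accrual
- `src/ptsdcea/outcomes.py` — CAPS-5 → EQ-VAS utilities, ICER and dominance,
  subgroup-mix effect reweighting
- `src/ptsdcea/sensitivity.py` — PSA, CEAC, one-way sweeps, tornado, threshold
  solving over dotted parameter paths
- `src/ptsdcea/synthetic.py` — random scenario generator and the
  microsimulation oracle
- `src/ptsdcea/cli.py`, `reporting.py` — `ptsdcea` command-line tool and
  report assembly
- `docs/methods.md` — modelling assumptions, parameter provenance and
  numerical choices
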