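# Methods

## Model structure

The package implements a cohort state-transition (Markov) model of PTSD
treatment with quarterly cycles over a 3-year horizon (12 cycles). Health
states per strategy are:

- `on_treatment(band, entry_band)` for every symptomatic CAPS-5 band at or
  below the entry severity — improvement moves at most one band per cycle
  (severe → moderate → mild → asymptomatic), so a patient entering severe can
  be on treatment in three bands, one entering mild in one;
- `dropped_out(band)` — out of therapy, frozen at the band of dropout;
- `asymptomatic` — absorbing apart from background death;
- `dead` — absorbing.

With the default four bands this gives 11 states. Per-cycle events compose
multiplicatively in the order **death → dropout → relapse → improvement**,
each conditional on the previous events not occurring. Mortality-first is the
standard convention; the remaining order follows treatment logic (you cannot
relapse out of a therapy you already left this cycle). Relapse strikes only
patients who have improved below their entry band — a patient still at entry
severity has no prior condition to revert to — and splits between retreatment
(return to `on_treatment` at the entry band) and dropout at the entry band.

### Band-crossing probability

A patient in a band of width *w* is taken to be uniformly distributed over
the band's CAPS-5 range. The per-cycle reduction is Normal(μ, σ) censored at
zero (a negative draw leaves the score unchanged rather than worsening it).
The probability of crossing below the band floor is

P(cross) = (1/w) ∫₀ʷ Q((d − μ)/σ) dd = (σ/w) [ zQ(z) − φ(z) ]ₐᵇ,

with Q the standard normal survival function, a = −μ/σ, b = (w − μ)/σ. The
closed form is exact and cheap (no quadrature in the hot path); σ = 0
degenerates to min(max(μ, 0), w)/w. Tests verify the closed form against
`scipy.integrate.quad` to 1e−6 and against 10⁷-draw Monte Carlo within
sampling error.

## Parameters

All costs are 2023 USD; probabilities are per quarterly cycle unless noted.

| parameter | default | units | rationale |
|---|---|---|---|
| severity bands | 60–80 / 40–59 / 20–39 / 0–19 | CAPS-5 | published banding; asymptomatic band completes the scale by contiguity |
| quarterly care cost | 5880 / 4900 / 3450 / 0 | USD | literature-derived care costs excluding therapy; asymptomatic carries none |
| psychotherapy course | 147 × 13.5 ≈ 1985 | USD | Medicare 90837 rate × mean session count |
| NF + psychotherapy course | 140 × 13.5 = 1890 | USD | Medicare 90876 rate × mean session count |
| pharmacotherapy | 1415 | USD/year | annual drug cost, pro-rated per cycle on treatment |
| dropout | 0.132 NF, 0.206 psych, 0.33 pharma | /cycle | trial-duration (≈ one quarter) non-adherence rates applied at the cycle scale; 0.206 is the midpoint of the reported 17.2–24% range |
| relapse | 0.14 NF/psych, 0.174 pharma | /cycle | reported relapse rates, applied at the cycle scale for symmetry with dropout |
| retreatment | 0.5 | probability | midpoint of the reported 20–80% range; swept in sensitivity analysis |
| effect | 7.01 (CI 1.36–12.66) NF, 6.25 ± 4.94 psych, 6.64 (CI 4.16–9.11) pharma, 13.2 (CI 10–16.4) amygdala-EFP | CAPS-5/course | meta-analytic reductions; the psychotherapy value is the military-mix-adjusted 6.25 |
| mortality | 0.0005 × {1.0, 1.3, 1.6, 2.0} | /cycle | background quarterly death probability at age 40–45 with a mild severity gradient; source values are not published, so fully configurable |
| initial mix | ⅓ severe / ⅓ moderate / ⅓ mild | proportions | entry states are reported without proportions; equal thirds is the uninformative choice |
| discount rate | 0.03 | /year | standard US health-economics practice |
| WTP | 0 | USD/QALY | cost-minimisation framing among non-dominated strategies |
| CAPS-5 → EQ-VAS map | EQ-VAS = 92 − 0.68 · CAPS-5 | — | calibrated so the asymptomatic midpoint maps near full health and the severe midpoint near EQ-VAS 44, consistent with published PTSD utility gradients; the source regression coefficients are unpublished, so the map is fully configurable. Comparative results depend on utility *differences*, not levels |

Dispersions written "±x" are treated as standard deviations; dispersions
given as 95% CIs are converted via SD = width/3.92. Band utilities use the
band midpoint (the cohort engine carries no continuous score) divided by 100.

### Therapy billing

Therapy courses are billed **once, at model entry** in the shipped scenarios
(`therapy_billing: first_course`), with the chronic drug cost pro-rated over
every on-treatment cycle. Two considerations drive this: the cost table
prices therapies per course, and re-billing a USD 1890 course every quarter
adds ≈ USD 4,400/year over the drug comparator — more than any feasible
care-cost divergence between initially identical cohorts, which would make
the intervention's reported early savings structurally impossible. The
engine's default for newly built scenarios is nevertheless per-cycle billing
(`every_cycle`), the conservative reading of "continued to be treated";
the flag switches between them. Limitation: in `first_course` mode,
retreatment after relapse does not re-bill a course (the cohort engine has no
cycle-indexed course counter), so therapy costs are slightly understated for
relapsing responders.

### Probability-scale conversions

`per_cycle_prob(p, k) = 1 − (1 − p)^(1/k)` converts a per-course or
per-period probability spanning *k* cycles to the cycle scale (constant
hazard). The shipped scenarios use k = 1 throughout: the printed dropout
rates are trial-duration (≈ 12-week ≈ one-quarter) figures, and relapse is
treated symmetrically. The `course_cycles` / `relapse_cycles` fields let a
scenario annualise any rate instead.

## Discounting and accrual

Discount factor (1 + r)^(−t·Δ) at the start of cycle t (Δ = cycle length in
years); costs and utilities are valued at start-of-cycle occupancy. A
`half_cycle` flag switches to mid-cycle valuation (mean of start/end
occupancy, discounting at t + ½); the default is off because the source
analysis does not mention one. QALYs are occupancy × band utility × Δ.
Cumulative results are reported at whole-year boundaries (cycles 4, 8, 12).

## Sensitivity analysis

Parameters are addressed by dotted paths
(`strategies.<name>.<field>`, `state_costs.<band>`, `mortality.<band>`,
`regression.<coef>`), a single namespace shared by the PSA, one-way sweeps,
tornado and threshold solver.

**PSA.** Each draw independently samples every entry of
`psa_distributions` (gamma for costs, beta for probabilities, normal for
effect means — the printed dispersion serves as the standard error of the
effect mean), runs both strategies and records (ΔC, ΔE). Probability draws
outside [0, 1] are resampled with a counter; a resample rate above 1% aborts.
Where no dispersion is printed, costs and the NF dropout use a 20% coefficient
of variation; the psychotherapy dropout and retreatment use their printed
ranges as 95% intervals. Quadrant classification: `dominant` (ΔC<0, ΔE>0),
`dominated` (ΔC>0, ΔE<0), `trade_off_ne`, `trade_off_sw`; ΔE = 0 draws count
as "cheaper" when ΔC < 0 but never as "dominant", and (0, 0) classifies as
`trade_off_ne`. The CEAC reports P(wtp·ΔE − ΔC > 0) over a WTP grid. Draws
are bit-reproducible for a fixed seed; parameters are sampled independently
(no correlation structure is published).

**Thresholds.** `find_threshold` brackets the sign change of incremental
discounted cost and solves the root with Brent's method (xtol 1e−12),
verifying |ΔC| at the root against the caller's tolerance; an interval
without a sign change raises "no threshold in range". Tests cross-check the
root against a dense grid scan.

**Tornado.** One-way endpoint runs per parameter, bars sorted by descending
influence on incremental cost; the default ranges sweep every dropout,
relapse, retreatment, effect and cost parameter ±25% (probabilities clipped
to [0, 0.99]).

## Microsimulation oracle

`synthetic.microsim` replays the engine's event ordering patient-by-patient
with continuous CAPS-5 scores. Under the default **memoryless** score model
the score is redrawn uniformly within the current band each cycle before the
censored-normal reduction is applied — exactly the assumption under which
the band-crossing probability is derived, making the microsimulation
distribution-identical to the cohort trace by construction and hence a valid
brute-force oracle. The **persistent** model carries reduced scores across
cycles (non-crossing survivors sit nearer the band floor, accelerating later
crossings); it is deliberately *not* equivalent to the cohort engine, and a
test demonstrates the two are statistically distinguishable at n = 20,000.

One fixed block of six draw vectors (death, dropout, relapse, retreatment,
score, effect) is consumed per cycle for all patients regardless of which
events fire, so simulations of two strategies under the same seed share
common random numbers, reducing the variance of paired comparisons. Oracle
agreement is asserted cell-wise at 3 binomial SE with a family-wise
allowance (≤ 1% of the ~1,400 cells, none beyond 4.5 SE), the correct
multiple-comparison form of a per-cell 3-SE band.

## Synthetic scenario generator

`random_scenario` draws structurally valid scenarios for property tests:
dropout on (0, 0.6) and relapse on (0, 0.3) via scaled beta draws,
retreatment uniform on the published 0.2–0.8 range, gamma care costs around
the published magnitudes, positive normal effect means (mean ≈ 8 CAPS-5
points), Dirichlet entry mixes, and method-of-moments PSA distributions. It
emulates the parameter *structure* of the analysis — not real-data features
such as parameter correlations, covariate-driven heterogeneity, age-dependent
mortality or non-stationary costs — so passing property tests demonstrates
internal consistency of the engine, not external validity of any scenario.

## Numerical choices

- Transition-matrix rows are validated to sum to 1 within 1e−12, trace
  conservation within 1e−9.
- Method-of-moments fits (gamma: shape = μ²/σ², scale = σ²/μ; beta:
  ν = μ(1−μ)/σ² − 1, α = μν, β = (1−μ)ν) recover analytic moments to 1e−10
  relative error; infeasible beta moments (σ² ≥ μ(1−μ)) raise.
- ICER is reported as undefined (`None`) when ΔE = 0, never ±∞.
- Degenerate effect σ = 0 is a point mass; per-course probability 1 is
  rejected (no finite per-cycle hazard).
- Mutating a sampled parameter bypasses cross-field revalidation by design
  (a sampled per-course cost need not match rate × sessions).

## Problem sizes

The test suite runs the microsimulation oracle at n = 50,000 patients per
strategy, the band-crossing Monte Carlo at 10⁷ draws per case (20 cases),
the PSA contract at n = 10,000 draws, grid-scan threshold verification at
10,000 points, and engine property checks over 50 generated scenarios; the
full suite completes in well under a minute on one CPU, and
`scripts/acceptance.py` in about half a minute.

## Known limitations

- Cohort-level model: no individual heterogeneity beyond what the
  microsimulation layer adds; utilities use band midpoints.
- Retreatment courses are not re-billed under `first_course` billing.
- Relapse is assumed equal across severity bands and only reachable from
  improved on-treatment states; dropped-out patients never re-enter care.
- Mortality is age-constant over the 3-year horizon.
- The base case reproduces the direction of the published comparisons except
  the pharmacotherapy comparison at year 1, where the up-front course cost
  and first-year care savings nearly cancel (≈ −0.5% of year-1 spend); the
  published year-1 saving evidently rests on unpublished appendix cost
  dynamics.
- No societal-perspective costs, no value-of-information analysis, no
  EQ-5D-index valuation sets.
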