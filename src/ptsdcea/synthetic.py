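"""Synthetic scenario generation and a patient-level microsimulation oracle.

``random_scenario`` draws structurally valid scenarios (beta-distributed
probabilities, gamma-distributed costs, normal effects with positive means)
for property tests.  ``microsim`` replays the cohort engine's event ordering
(death -> dropout -> relapse/retreatment -> improvement) patient by patient
with continuous CAPS-5 scores, providing the brute-force oracle the cohort
trace is checked against.

Score models
------------
``memoryless`` (default): each cycle the patient's score is redrawn uniformly
within the current band before the effect draw is applied, exactly the
assumption under which the engine's band-crossing probability is derived —
the two layers are distribution-identical by construction.  ``persistent``
carries the reduced score across cycles (more realistic; intentionally *not*
equivalent to the cohort engine, so never used as the oracle).

One fixed block of uniform/normal draws is consumed per patient per cycle
regardless of which events fire, so two strategies simulated with the same
seed share common random numbers for paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    HealthState,
    build_state_space,
    discount_factor,
    per_cycle_prob,
    state_cost_vector,
    state_utility_vector,
)
from .outcomes import RegressionMap
from .scenario import (
    MortalityTable,
    Scenario,
    StateCostTable,
    TherapyProfile,
    fit_distribution,
)


@dataclass
class Patient:
    """Individual-level counterpart of one cohort member (for ledger export)."""

    caps5: float
    state: HealthState
    entry_band: str
    alive: bool = True
    on_treatment: bool = True
    cost_ledger: float = 0.0
    qaly_ledger: float = 0.0


def random_scenario(seed: int) -> Scenario:
    """A valid two-strategy scenario with realistic PTSD parameter structure.

    Probabilities come from scaled beta draws (dropout support (0, 0.6),
    relapse (0, 0.3), retreatment the 0.2-0.8 range), costs from gamma
    families around the magnitudes seen in US care-cost data, and effects
    from positive-mean normal families.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)

    def make_strategy(name: str) -> TherapyProfile:
        per_session = float(rng.gamma((150 / 40) ** 2, 40**2 / 150))
        sessions = float(np.round(rng.uniform(8, 16) * 2) / 2)
        per_course = round(per_session * sessions, 2)
        return TherapyProfile(
            name=name,
            per_session_cost=round(per_session, 2),
            sessions_per_course=sessions,
            per_course_cost=per_course,
            annual_drug_cost=float(np.round(rng.gamma(16, 1400 / 16), 2))
            if rng.random() < 0.5 else 0.0,
            course_cycles=1,
            dropout_course_prob=float(0.6 * rng.beta(2, 2)),
            relapse_prob=float(0.3 * rng.beta(2, 2)),
            relapse_cycles=1,
            retreatment_prob=float(rng.uniform(0.2, 0.8)),
            effect_mean=float(rng.gamma((8 / 3) ** 2, 9 / 8)),
            effect_dispersion=float(rng.uniform(0.5, 5.0)),
            effect_dispersion_kind="sd",
        )

    strategies = [make_strategy("treatment_a"), make_strategy("treatment_b")]
    base_costs = {"severe": 5880.0, "moderate": 4900.0, "mild": 3450.0}
    state_costs = {
        band: float(np.round(rng.gamma(25, mean / 25), 2))
        for band, mean in base_costs.items()
    }
    state_costs["asymptomatic"] = 0.0
    base_death = float(rng.uniform(0.0002, 0.001))
    mortality = {
        "asymptomatic": base_death,
        "mild": base_death * 1.3,
        "moderate": base_death * 1.6,
        "severe": base_death * 2.0,
    }
    mix = rng.dirichlet([1.0, 1.0, 1.0])
    initial = {
        "severe": float(mix[0]),
        "moderate": float(mix[1]),
        "mild": float(mix[2]),
    }
    psa = {
        f"strategies.{s.name}.dropout_course_prob": fit_distribution(
            max(s.dropout_course_prob, 1e-3), 0.2 * max(s.dropout_course_prob, 1e-3),
            family="beta",
        )
        for s in strategies
    }
    psa.update({
        f"strategies.{s.name}.effect_mean": fit_distribution(
            s.effect_mean, max(s.effect_dispersion, 0.5), family="normal"
        )
        for s in strategies
    })
    return Scenario(
        name=f"random_{seed}",
        strategies=strategies,
        state_costs=StateCostTable(quarterly_cost_by_band=state_costs),
        mortality=MortalityTable(quarterly_death_prob_by_band=mortality),
        initial_distribution=initial,
        regression=RegressionMap(
            intercept=float(rng.uniform(85, 95)),
            slope=float(rng.uniform(-0.9, -0.4)),
        ),
        psa_distributions=psa,
        seed=int(seed),
    )


@dataclass
class MicrosimResult:
    """Per-cycle means and standard errors from a patient-level simulation."""

    n: int
    seed: int
    states: list[HealthState]
    mean_occupancy: np.ndarray   # (horizon + 1, n_states)
    occupancy_se: np.ndarray
    mean_cost: np.ndarray        # discounted, per cycle
    cost_se: np.ndarray
    mean_qaly: np.ndarray
    qaly_se: np.ndarray
    total_cost_mean: float = 0.0
    total_cost_se: float = 0.0
    total_qaly_mean: float = 0.0
    total_qaly_se: float = 0.0

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.mean_occupancy.shape[0]):
            for j, s in enumerate(self.states):
                rows.append({
                    "cycle": t,
                    "state": s.label,
                    "occupancy": self.mean_occupancy[t, j],
                    "se": self.occupancy_se[t, j],
                })
        return pd.DataFrame(rows)


def microsim(
    scenario: Scenario,
    strategy: int | str | TherapyProfile = 0,
    n: int = 10_000,
    seed: int = 0,
    score_model: str = "memoryless",
) -> MicrosimResult:
    """Simulate ``n`` patients cycle by cycle under one strategy.

    Event probabilities and ordering are identical to the cohort engine's
    transition matrix; see the module docstring for the score models.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if score_model not in ("memoryless", "persistent"):
        raise ValueError("score_model must be 'memoryless' or 'persistent'")
    if not isinstance(strategy, TherapyProfile):
        strategy = scenario.strategy(strategy)

    states = build_state_space(scenario)
    state_index = {s: j for j, s in enumerate(states)}
    sym = scenario.symptomatic_bands()          # worst first
    n_sym = len(sym)
    low = np.array([b.caps5_low for b in sym], dtype=float)
    high = np.array([b.caps5_high for b in sym], dtype=float)
    death_by_band = np.array([scenario.mortality.prob(b.label) for b in sym])
    death_asym = scenario.mortality.prob("asymptomatic")

    p_drop = per_cycle_prob(strategy.dropout_course_prob, strategy.course_cycles)
    p_rel = per_cycle_prob(strategy.relapse_prob, strategy.relapse_cycles)
    retreat = strategy.retreatment_prob
    eff_mean, eff_sd = strategy.effect_mean, strategy.effect_sd

    # patient state encoding
    ON, DROP, ASYM, DEADC = 0, 1, 2, 3
    rng = np.random.default_rng(seed)
    horizon = scenario.horizon_cycles

    # initial band assignment (band index into sym; asymptomatic entry allowed)
    labels = [b.label for b in sym] + ["asymptomatic"]
    probs = np.array([scenario.initial_distribution.get(lbl, 0.0) for lbl in labels])
    assignment = rng.choice(len(labels), size=n, p=probs / probs.sum())
    kind = np.where(assignment < n_sym, ON, ASYM)
    band = np.where(assignment < n_sym, assignment, 0)
    entry = band.copy()
    score = low[band] + rng.random(n) * (high[band] - low[band])

    utils = state_utility_vector(scenario, states)
    static_costs = (
        state_cost_vector(scenario, strategy, 0, states)
        if scenario.therapy_billing == "every_cycle" else None
    )

    def state_codes() -> np.ndarray:
        codes = np.empty(n, dtype=int)
        for j in range(n_sym):
            for e in range(j + 1):
                mask = (kind == ON) & (band == j) & (entry == e)
                codes[mask] = state_index[
                    HealthState(kind="on_treatment", band=sym[j].label,
                                entry_band=sym[e].label)
                ]
            mask = (kind == DROP) & (band == j)
            codes[mask] = state_index[HealthState(kind="dropped_out",
                                                  band=sym[j].label)]
        codes[kind == ASYM] = state_index[HealthState(kind="asymptomatic")]
        codes[kind == DEADC] = state_index[HealthState(kind="dead")]
        return codes

    n_states = len(states)
    occupancy = np.zeros((horizon + 1, n_states))
    mean_cost = np.zeros(horizon)
    cost_se = np.zeros(horizon)
    mean_qaly = np.zeros(horizon)
    qaly_se = np.zeros(horizon)
    patient_cost = np.zeros(n)
    patient_qaly = np.zeros(n)

    for t in range(horizon):
        codes = state_codes()
        occupancy[t] = np.bincount(codes, minlength=n_states) / n
        costs_t = (static_costs if static_costs is not None
                   else state_cost_vector(scenario, strategy, t, states))
        df = discount_factor(scenario.annual_discount_rate, t,
                             scenario.cycle_length_years)
        c = costs_t[codes] * df
        q = utils[codes] * scenario.cycle_length_years * df
        mean_cost[t] = c.mean()
        cost_se[t] = c.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        mean_qaly[t] = q.mean()
        qaly_se[t] = q.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        patient_cost += c
        patient_qaly += q

        # fixed draw layout per cycle -> common random numbers across strategies
        u_death = rng.random(n)
        u_drop = rng.random(n)
        u_rel = rng.random(n)
        u_retreat = rng.random(n)
        u_score = rng.random(n)
        z_effect = rng.standard_normal(n)

        # death
        p_die = np.zeros(n)
        on_or_drop = (kind == ON) | (kind == DROP)
        p_die[on_or_drop] = death_by_band[band[on_or_drop]]
        p_die[kind == ASYM] = death_asym
        dies = (kind != DEADC) & (u_death < p_die)
        kind[dies] = DEADC

        # dropout (on-treatment survivors)
        on = kind == ON
        drops = on & (u_drop < p_drop)
        kind[drops] = DROP

        # relapse, only from improved states (band strictly better than entry)
        on = kind == ON
        improved = on & (band > entry)
        relapses = improved & (u_rel < p_rel)
        retreated = relapses & (u_retreat < retreat)
        not_retreated = relapses & ~retreated
        band[retreated] = entry[retreated]
        score[retreated] = (low[band[retreated]]
                           + u_score[retreated]
                           * (high[band[retreated]] - low[band[retreated]]))
        kind[not_retreated] = DROP
        band[not_retreated] = entry[not_retreated]

        # improvement via continuous score reduction
        at_risk = (kind == ON) & ~relapses
        if score_model == "memoryless":
            score[at_risk] = (low[band[at_risk]]
                              + u_score[at_risk]
                              * (high[band[at_risk]] - low[band[at_risk]]))
        reduction = np.maximum(0.0, eff_mean + eff_sd * z_effect)
        new_score = score.copy()
        new_score[at_risk] = score[at_risk] - reduction[at_risk]
        crosses = at_risk & (new_score < low[band])
        to_asym = crosses & (band == n_sym - 1)
        to_lower = crosses & ~to_asym
        kind[to_asym] = ASYM
        band[to_lower] += 1
        if score_model == "persistent":
            # carry the reduced score, clamped into the new band (one band/cycle)
            score[to_lower] = np.clip(new_score[to_lower],
                                      low[band[to_lower]], high[band[to_lower]])
            stay = at_risk & ~crosses
            score[stay] = new_score[stay]
        else:
            score[to_lower] = (low[band[to_lower]]
                               + u_score[to_lower]
                               * (high[band[to_lower]] - low[band[to_lower]]))

    codes = state_codes()
    occupancy[horizon] = np.bincount(codes, minlength=n_states) / n
    occupancy_se = np.sqrt(occupancy * (1 - occupancy) / n)

    return MicrosimResult(
        n=n, seed=seed, states=states,
        mean_occupancy=occupancy, occupancy_se=occupancy_se,
        mean_cost=mean_cost, cost_se=cost_se,
        mean_qaly=mean_qaly, qaly_se=qaly_se,
        total_cost_mean=float(patient_cost.mean()),
        total_cost_se=float(patient_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        total_qaly_mean=float(patient_qaly.mean()),
        total_qaly_se=float(patient_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def microsim_ledger(
    scenario: Scenario,
    strategy: int | str | TherapyProfile = 0,
    n: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-patient, per-cycle ledger (patient, cycle, state, caps5, cost,
    qaly) for debugging small simulations.

    Uses the same event semantics as :func:`microsim` but a simple per-patient
    loop; not stream-identical to the vectorised simulator.
    """
    if not isinstance(strategy, TherapyProfile):
        strategy = scenario.strategy(strategy)
    states = build_state_space(scenario)
    utils = state_utility_vector(scenario, states)
    sym = scenario.symptomatic_bands()
    sym_labels = [b.label for b in sym]
    rng = np.random.default_rng(seed)
    p_drop = per_cycle_prob(strategy.dropout_course_prob, strategy.course_cycles)
    p_rel = per_cycle_prob(strategy.relapse_prob, strategy.relapse_cycles)
    labels = sym_labels + ["asymptomatic"]
    init_p = np.array([scenario.initial_distribution.get(lbl, 0.0) for lbl in labels])
    rows = []
    for pid in range(n):
        start = labels[rng.choice(len(labels), p=init_p / init_p.sum())]
        if start == "asymptomatic":
            patient = Patient(caps5=scenario.band(start).midpoint,
                              state=HealthState(kind="asymptomatic"),
                              entry_band=start, on_treatment=False)
        else:
            b = scenario.band(start)
            patient = Patient(caps5=float(rng.uniform(b.caps5_low, b.caps5_high)),
                              state=HealthState(kind="on_treatment", band=start,
                                                entry_band=start),
                              entry_band=start)
        for t in range(scenario.horizon_cycles):
            s = patient.state
            j = states.index(s)
            df = discount_factor(scenario.annual_discount_rate, t,
                                 scenario.cycle_length_years)
            cost = state_cost_vector(scenario, strategy, t, states)[j] * df
            qaly = utils[j] * scenario.cycle_length_years * df
            if patient.alive:
                patient.cost_ledger += cost
                patient.qaly_ledger += qaly
            rows.append({"patient": pid, "cycle": t, "state": s.label,
                         "caps5": patient.caps5, "cost": cost if patient.alive else 0.0,
                         "qaly": qaly if patient.alive else 0.0})
            # transition (same composition as the engine)
            if s.kind == "dead":
                continue
            band_lbl = "asymptomatic" if s.kind == "asymptomatic" else s.band
            if rng.random() < scenario.mortality.prob(band_lbl):
                patient.state = HealthState(kind="dead")
                patient.alive = False
                continue
            if s.kind != "on_treatment":
                continue
            if rng.random() < p_drop:
                patient.state = HealthState(kind="dropped_out", band=s.band)
                patient.on_treatment = False
                continue
            if s.band != s.entry_band and rng.random() < p_rel:
                if rng.random() < strategy.retreatment_prob:
                    eb = scenario.band(s.entry_band)
                    patient.state = HealthState(kind="on_treatment", band=s.entry_band,
                                                entry_band=s.entry_band)
                    patient.caps5 = float(rng.uniform(eb.caps5_low, eb.caps5_high))
                else:
                    patient.state = HealthState(kind="dropped_out", band=s.entry_band)
                    patient.on_treatment = False
                continue
            b = scenario.band(s.band)
            x = float(rng.uniform(b.caps5_low, b.caps5_high))
            r = max(0.0, float(rng.normal(strategy.effect_mean, strategy.effect_sd)))
            if x - r < b.caps5_low:
                pos = sym_labels.index(s.band)
                if pos == len(sym_labels) - 1:
                    patient.state = HealthState(kind="asymptomatic")
                    patient.caps5 = scenario.band("asymptomatic").midpoint
                    patient.on_treatment = False
                else:
                    nb = scenario.band(sym_labels[pos + 1])
                    patient.state = HealthState(kind="on_treatment",
                                                band=nb.label, entry_band=s.entry_band)
                    patient.caps5 = float(rng.uniform(nb.caps5_low, nb.caps5_high))
    return pd.DataFrame(rows)
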