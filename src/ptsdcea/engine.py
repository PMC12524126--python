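"""Cohort state-transition engine: transition matrices, traces and accrual.

Health states per strategy are:

* ``on_treatment(band, entry_band)`` for every symptomatic band at or below
  the entry severity (improvement moves at most one band per cycle, so a
  patient entering severe can be on treatment at severe, moderate or mild);
* ``dropped_out(band)`` — out of therapy, frozen at the band of dropout;
* ``asymptomatic`` — absorbing apart from background death;
* ``dead`` — absorbing.

Per-cycle events compose multiplicatively in the order death -> dropout ->
relapse (with a retreatment split) -> improvement, each conditional on the
previous events not occurring.  Relapse only strikes patients who have
improved below their entry band; retreated relapsers re-enter treatment at
the entry band, the rest drop out there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import RegressionMap, band_utility
from .scenario import Scenario, SeverityBand, TherapyProfile

_SQRT2 = math.sqrt(2.0)


def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / _SQRT2)


def _norm_pdf(x: float) -> float:
    return math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class HealthState:
    kind: str  # on_treatment | dropped_out | asymptomatic | dead
    band: str | None = None
    entry_band: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "on_treatment":
            return f"on_treatment[{self.band}|entry={self.entry_band}]"
        if self.kind == "dropped_out":
            return f"dropped_out[{self.band}]"
        return self.kind


ASYMPTOMATIC = HealthState(kind="asymptomatic")
DEAD = HealthState(kind="dead")


def build_state_space(scenario: Scenario) -> list[HealthState]:
    """Deterministic state ordering shared by the engine and the microsim."""
    sym = scenario.symptomatic_bands()  # worst first
    states: list[HealthState] = []
    for i, entry in enumerate(sym):
        for band in sym[i:]:
            states.append(
                HealthState(kind="on_treatment", band=band.label, entry_band=entry.label)
            )
    for band in sym:
        states.append(HealthState(kind="dropped_out", band=band.label))
    states.append(ASYMPTOMATIC)
    states.append(DEAD)
    return states


def per_cycle_prob(course_prob: float, cycles_per_course: float) -> float:
    """Convert a per-course probability to the per-cycle scale.

    Uses the constant-hazard identity 1 - (1 - p)**(1/k), whose inverse over
    ``k`` cycles recovers the original per-course probability.
    """
    if not 0 <= course_prob < 1:
        raise ValueError("course_prob must lie in [0, 1); p = 1 is degenerate")
    if cycles_per_course < 1:
        raise ValueError("cycles_per_course must be >= 1")
    return 1.0 - (1.0 - course_prob) ** (1.0 / cycles_per_course)


def band_crossing_prob(band: SeverityBand, effect: tuple[float, float]) -> float:
    """Probability a patient in ``band`` crosses below its lower bound in a cycle.

    The patient's score is uniform on [caps5_low, caps5_high]; the per-cycle
    reduction is max(0, Normal(mean, sd)) — negative draws do not worsen the
    score.  Closed form: with d = score - caps5_low ~ U(0, w),

        P(cross) = (1/w) * Int_0^w P(N(mean, sd) > d) dd
                 = (sd/w) * [z*Q(z) - phi(z)]_{a}^{b},  a = -mean/sd, b = (w-mean)/sd

    where Q is the standard normal survival function.
    """
    mean, sd = effect
    if sd < 0:
        raise ValueError("effect sd must be non-negative")
    if band.label == "asymptomatic":
        raise ValueError("crossing probability undefined for the asymptomatic band")
    w = band.width
    if w == 0:
        # degenerate band: score is exactly caps5_low; any positive reduction crosses
        return 1.0 - _norm_cdf((0.0 - mean) / sd) if sd > 0 else float(mean > 0)

    def antideriv(z: float) -> float:
        q = 1.0 - _norm_cdf(z)
        return z * q - _norm_pdf(z)

    if sd == 0:
        return min(max(mean, 0.0), w) / w
    a = (0.0 - mean) / sd
    b = (w - mean) / sd
    p = sd / w * (antideriv(b) - antideriv(a))
    return min(1.0, max(0.0, p))


@dataclass
class TransitionMatrix:
    states: list[HealthState]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = self.probs
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-15):
            bad = int(np.argmax((p < -1e-15) | (p > 1 + 1e-15)) // p.shape[1])
            raise ValueError(
                f"transition probability outside [0, 1] in row "
                f"{self.states[bad].label}"
            )
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"row for state {self.states[bad].label} sums to {rows[bad]!r}"
            )

    def index(self, state: HealthState) -> int:
        return self.states.index(state)


def _per_cycle_rates(strategy: TherapyProfile) -> tuple[float, float]:
    p_drop = per_cycle_prob(strategy.dropout_course_prob, strategy.course_cycles)
    p_rel = per_cycle_prob(strategy.relapse_prob, strategy.relapse_cycles)
    return p_drop, p_rel


def build_transition_matrix(
    scenario: Scenario, strategy: TherapyProfile
) -> TransitionMatrix:
    """Per-cycle transition matrix for one strategy under a scenario."""
    states = build_state_space(scenario)
    idx = {s: i for i, s in enumerate(states)}
    sym = scenario.symptomatic_bands()
    sym_labels = [b.label for b in sym]
    n = len(states)
    P = np.zeros((n, n))

    p_drop, p_rel = _per_cycle_rates(strategy)
    retreat = strategy.retreatment_prob
    effect = (strategy.effect_mean, strategy.effect_sd)
    p_cross = {b.label: band_crossing_prob(b, effect) for b in sym}
    p_death = {lbl: scenario.mortality.prob(lbl) for lbl in sym_labels}
    p_death["asymptomatic"] = scenario.mortality.prob("asymptomatic")

    i_dead = idx[DEAD]
    i_asym = idx[ASYMPTOMATIC]

    for state in states:
        i = idx[state]
        if state.kind == "dead":
            P[i, i_dead] = 1.0
            continue
        if state.kind == "asymptomatic":
            pd_ = p_death["asymptomatic"]
            P[i, i_dead] = pd_
            P[i, i_asym] = 1.0 - pd_
            continue
        pd_ = p_death[state.band]
        if state.kind == "dropped_out":
            P[i, i_dead] = pd_
            P[i, i] = 1.0 - pd_
            continue
        # on_treatment(band, entry)
        survive = 1.0 - pd_
        P[i, i_dead] = pd_
        drop_mass = survive * p_drop
        P[i, idx[HealthState(kind="dropped_out", band=state.band)]] += drop_mass
        remaining = survive - drop_mass
        if state.band != state.entry_band:
            rel_mass = remaining * p_rel
            P[i, idx[HealthState(kind="on_treatment", band=state.entry_band,
                                 entry_band=state.entry_band)]] += rel_mass * retreat
            P[i, idx[HealthState(kind="dropped_out", band=state.entry_band)]] += (
                rel_mass * (1.0 - retreat)
            )
            remaining -= rel_mass
        cross_mass = remaining * p_cross[state.band]
        band_pos = sym_labels.index(state.band)
        if band_pos == len(sym_labels) - 1:  # mildest symptomatic band
            P[i, i_asym] += cross_mass
        else:
            P[i, idx[HealthState(kind="on_treatment",
                                 band=sym_labels[band_pos + 1],
                                 entry_band=state.entry_band)]] += cross_mass
        P[i, i] += remaining - cross_mass

    return TransitionMatrix(states=states, probs=P)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy proportions; row 0 is the initial cohort."""

    states: list[HealthState]
    occupancy: np.ndarray  # (horizon_cycles + 1, n_states)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.occupancy.shape[0]):
            for s, occ in zip(self.states, self.occupancy[t]):
                rows.append({"cycle": t, "state": s.label, "occupancy": occ})
        return pd.DataFrame(rows)


def initial_occupancy(scenario: Scenario, states: list[HealthState]) -> np.ndarray:
    occ = np.zeros(len(states))
    for band, proportion in scenario.initial_distribution.items():
        if band == "asymptomatic":
            target = ASYMPTOMATIC
        else:
            target = HealthState(kind="on_treatment", band=band, entry_band=band)
        occ[states.index(target)] = proportion
    return occ


def run_cohort(scenario: Scenario, strategy: TherapyProfile) -> CohortTrace:
    """Iterate the cohort over the horizon; trace has horizon_cycles + 1 rows."""
    tm = build_transition_matrix(scenario, strategy)
    horizon = scenario.horizon_cycles
    occ = np.zeros((horizon + 1, len(tm.states)))
    occ[0] = initial_occupancy(scenario, tm.states)
    for t in range(horizon):
        occ[t + 1] = occ[t] @ tm.probs
    return CohortTrace(states=tm.states, occupancy=occ)


def discount_factor(
    annual_rate: float, cycle_index: float, cycle_length_years: float
) -> float:
    """(1 + r)^(-t * cycle_length); 1.0 at cycle 0 or zero rate."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + annual_rate) ** (-cycle_index * cycle_length_years)


def state_cost_vector(
    scenario: Scenario,
    strategy: TherapyProfile,
    cycle: int,
    states: list[HealthState] | None = None,
) -> np.ndarray:
    """Per-cycle USD cost of each state at a given cycle (therapy + care)."""
    if states is None:
        states = build_state_space(scenario)
    course_component = strategy.per_course_cost / strategy.course_cycles
    if scenario.therapy_billing == "first_course" and cycle >= strategy.course_cycles:
        course_component = 0.0
    drug_component = strategy.annual_drug_cost * scenario.cycle_length_years
    costs = np.zeros(len(states))
    for i, s in enumerate(states):
        if s.kind == "dead":
            continue
        if s.kind == "asymptomatic":
            costs[i] = scenario.state_costs.cost("asymptomatic")
        elif s.kind == "dropped_out":
            costs[i] = scenario.state_costs.cost(s.band)
        else:  # on_treatment
            costs[i] = (
                scenario.state_costs.cost(s.band) + course_component + drug_component
            )
    return costs


def state_utility_vector(scenario: Scenario, states: list[HealthState]) -> np.ndarray:
    reg: RegressionMap = scenario.regression
    utils = np.zeros(len(states))
    for i, s in enumerate(states):
        if s.kind == "dead":
            continue
        band = "asymptomatic" if s.kind == "asymptomatic" else s.band
        utils[i] = band_utility(reg, scenario.band(band))
    return utils


@dataclass
class RunResult:
    """Discounted and undiscounted per-cycle cost and QALY streams."""

    cost: np.ndarray        # undiscounted, per cycle
    cost_disc: np.ndarray
    qaly: np.ndarray
    qaly_disc: np.ndarray
    cycle_length_years: float
    strategy_name: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    def cumulative_by_year(self) -> dict[int, tuple[float, float]]:
        """Cumulative discounted (cost, QALY) at the end of each whole year."""
        cycles_per_year = int(round(1.0 / self.cycle_length_years))
        out: dict[int, tuple[float, float]] = {}
        n_years = self.n_cycles // cycles_per_year
        for year in range(1, n_years + 1):
            k = year * cycles_per_year
            out[year] = (float(self.cost_disc[:k].sum()),
                         float(self.qaly_disc[:k].sum()))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "cost": self.cost,
            "cost_discounted": self.cost_disc,
            "qaly": self.qaly,
            "qaly_discounted": self.qaly_disc,
        })


def accrue(
    trace: CohortTrace, scenario: Scenario, strategy: TherapyProfile
) -> RunResult:
    """Accrue per-cycle costs and QALYs over a cohort trace.

    The base engine values each cycle at its start-of-cycle occupancy; with
    ``scenario.half_cycle`` the mean of start and end occupancy is used and
    discounting is applied at cycle midpoints.
    """
    horizon = trace.occupancy.shape[0] - 1
    utils = state_utility_vector(scenario, trace.states)
    static_costs = (
        state_cost_vector(scenario, strategy, 0, trace.states)
        if scenario.therapy_billing == "every_cycle"
        else None
    )
    cost = np.zeros(horizon)
    qaly = np.zeros(horizon)
    cost_disc = np.zeros(horizon)
    qaly_disc = np.zeros(horizon)
    for t in range(horizon):
        if scenario.half_cycle:
            occ = 0.5 * (trace.occupancy[t] + trace.occupancy[t + 1])
            df = discount_factor(scenario.annual_discount_rate, t + 0.5,
                                 scenario.cycle_length_years)
        else:
            occ = trace.occupancy[t]
            df = discount_factor(scenario.annual_discount_rate, t,
                                 scenario.cycle_length_years)
        costs_t = (
            static_costs
            if static_costs is not None
            else state_cost_vector(scenario, strategy, t, trace.states)
        )
        cost[t] = float(occ @ costs_t)
        qaly[t] = float(occ @ utils) * scenario.cycle_length_years
        cost_disc[t] = cost[t] * df
        qaly_disc[t] = qaly[t] * df
    return RunResult(cost=cost, cost_disc=cost_disc, qaly=qaly, qaly_disc=qaly_disc,
                     cycle_length_years=scenario.cycle_length_years,
                     strategy_name=strategy.name)


def run_strategy(
    scenario: Scenario, strategy: int | str | TherapyProfile = 0
) -> tuple[CohortTrace, RunResult]:
    """Convenience: trace and accrued result for one strategy of a scenario."""
    if not isinstance(strategy, TherapyProfile):
        strategy = scenario.strategy(strategy)
    trace = run_cohort(scenario, strategy)
    return trace, accrue(trace, scenario, strategy)
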