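"""Probabilistic and deterministic sensitivity analysis.

Parameters are addressed by dotted paths over the scenario namespace, e.g.
``strategies.psychotherapy.dropout_course_prob``, ``state_costs.mild`` or
``regression.slope``; the same paths drive the probabilistic sensitivity
analysis (PSA), one-way sweeps, tornado diagrams and threshold solving.

PSA follows the usual health-economics recipe: every uncertain parameter is
sampled independently from its distribution, both strategies are run on the
sampled scenario, and the paired (delta cost, delta QALY) draws populate the
cost-effectiveness plane.  Probability parameters sampled outside [0, 1] are
resampled (with a counter; a rate above 1% aborts the analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import outcomes
from .engine import run_strategy
from .scenario import Scenario, DistributionSpec

#: Scenario fields addressable as bare top-level paths.
_SCALAR_FIELDS = ("annual_discount_rate", "wtp_per_qaly", "cycle_length_years")

#: Strategy fields that are probabilities (used for the PSA resampling rule).
_PROB_FIELDS = ("dropout_course_prob", "relapse_prob", "retreatment_prob")


def valid_paths(scenario: Scenario) -> list[str]:
    """All dotted parameter paths addressable on this scenario."""
    paths: list[str] = []
    numeric_strategy_fields = (
        "per_session_cost", "sessions_per_course", "per_course_cost",
        "annual_drug_cost", "dropout_course_prob", "relapse_prob",
        "retreatment_prob", "effect_mean", "effect_dispersion",
    )
    for s in scenario.strategies:
        paths += [f"strategies.{s.name}.{f}" for f in numeric_strategy_fields]
    for band in scenario.state_costs.quarterly_cost_by_band:
        paths.append(f"state_costs.{band}")
    for band in scenario.mortality.quarterly_death_prob_by_band:
        paths.append(f"mortality.{band}")
    paths += ["regression.intercept", "regression.slope"]
    paths += list(_SCALAR_FIELDS)
    return paths


def _unknown(scenario: Scenario, path: str) -> KeyError:
    return KeyError(
        f"unknown parameter path {path!r}; valid paths: {valid_paths(scenario)}"
    )


def get_param(scenario: Scenario, path: str) -> float:
    parts = path.split(".")
    try:
        if parts[0] == "strategies" and len(parts) == 3:
            return float(getattr(scenario.strategy(parts[1]), parts[2]))
        if parts[0] == "state_costs" and len(parts) == 2:
            return float(scenario.state_costs.quarterly_cost_by_band[parts[1]])
        if parts[0] == "mortality" and len(parts) == 2:
            return float(scenario.mortality.quarterly_death_prob_by_band[parts[1]])
        if parts[0] == "regression" and len(parts) == 2:
            return float(getattr(scenario.regression, parts[1]))
        if len(parts) == 1 and parts[0] in _SCALAR_FIELDS:
            return float(getattr(scenario, parts[0]))
    except (KeyError, AttributeError):
        raise _unknown(scenario, path) from None
    raise _unknown(scenario, path)


def _set_param_inplace(scenario: Scenario, path: str, value: float) -> None:
    parts = path.split(".")
    try:
        if parts[0] == "strategies" and len(parts) == 3:
            strategy = scenario.strategy(parts[1])
            if not hasattr(strategy, parts[2]):
                raise KeyError(path)
            object.__setattr__(strategy, parts[2], value)
            return
        if parts[0] == "state_costs" and len(parts) == 2:
            costs = scenario.state_costs.quarterly_cost_by_band
            if parts[1] not in costs:
                raise KeyError(path)
            costs[parts[1]] = value
            return
        if parts[0] == "mortality" and len(parts) == 2:
            probs = scenario.mortality.quarterly_death_prob_by_band
            if parts[1] not in probs:
                raise KeyError(path)
            probs[parts[1]] = value
            return
        if parts[0] == "regression" and len(parts) == 2:
            if not hasattr(scenario.regression, parts[1]):
                raise KeyError(path)
            object.__setattr__(scenario.regression, parts[1], value)
            return
        if len(parts) == 1 and parts[0] in _SCALAR_FIELDS:
            object.__setattr__(scenario, parts[0], value)
            return
    except KeyError:
        raise _unknown(scenario, path) from None
    raise _unknown(scenario, path)


def with_param(scenario: Scenario, path: str, value: float) -> Scenario:
    """A deep copy of the scenario with one parameter replaced.

    Deliberately bypasses cross-field revalidation (a sampled per-course cost
    need not match per-session x sessions).
    """
    get_param(scenario, path)  # raises on unknown path
    new = scenario.model_copy(deep=True)
    _set_param_inplace(new, path, value)
    return new


def is_probability_path(path: str) -> bool:
    parts = path.split(".")
    if parts[0] == "mortality":
        return True
    return parts[0] == "strategies" and len(parts) == 3 and parts[2] in _PROB_FIELDS


def _incremental(scenario: Scenario, comparator: int | str):
    _, a = run_strategy(scenario, 0)
    _, b = run_strategy(scenario, comparator)
    return a, b


@dataclass
class PSAResult:
    """Paired (delta cost, delta QALY) Monte Carlo draws and their summary."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n: int
    seed: int
    comparator: str
    resample_count: int = 0
    ceac: dict[float, float] = field(default_factory=dict)

    @property
    def classifications(self) -> list[str]:
        return [
            outcomes.classify_quadrant(dc, de)
            for dc, de in zip(self.delta_cost, self.delta_qaly)
        ]

    @property
    def fraction_dominant(self) -> float:
        return float(np.mean((self.delta_cost < 0) & (self.delta_qaly > 0)))

    @property
    def fraction_cheaper(self) -> float:
        return float(np.mean(self.delta_cost < 0))

    @property
    def fraction_dominated(self) -> float:
        return float(np.mean((self.delta_cost > 0) & (self.delta_qaly < 0)))

    def quadrant_fractions(self) -> dict[str, float]:
        labels = self.classifications
        return {
            q: labels.count(q) / self.n
            for q in (outcomes.DOMINANT, outcomes.DOMINATED,
                      outcomes.TRADE_OFF_NE, outcomes.TRADE_OFF_SW)
        }

    def ceac_at(self, wtp: float) -> float:
        """Probability the intervention is preferred at a WTP threshold."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "quadrant": self.classifications,
        })


def run_psa(
    scenario: Scenario,
    n: int = 10_000,
    seed: int | None = None,
    comparator: int | str = 1,
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 100_001, 10_000)),
    max_resample_rate: float = 0.01,
) -> PSAResult:
    """Monte Carlo PSA of strategies[0] against a comparator.

    Bit-reproducible for a fixed seed: the draw order is the (insertion)
    order of ``scenario.psa_distributions``.
    """
    if not scenario.psa_distributions:
        raise ValueError("scenario defines no psa_distributions")
    for path in scenario.psa_distributions:
        get_param(scenario, path)  # validate targets exist up front
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    comparator_name = scenario.strategy(comparator).name

    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    resamples = 0
    total_samples = 0
    for i in range(n):
        draw = scenario.model_copy(deep=True)
        for path, spec in scenario.psa_distributions.items():
            value = float(spec.sample(rng))
            total_samples += 1
            if is_probability_path(path):
                tries = 0
                while not 0.0 <= value <= 1.0:
                    value = float(spec.sample(rng))
                    resamples += 1
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError(
                            f"cannot sample a valid probability for {path}"
                        )
            _set_param_inplace(draw, path, value)
        a, b = _incremental(draw, comparator)
        delta_cost[i] = a.total_cost - b.total_cost
        delta_qaly[i] = a.total_qaly - b.total_qaly

    if total_samples and resamples / total_samples > max_resample_rate:
        raise RuntimeError(
            f"PSA resample rate {resamples / total_samples:.2%} exceeds "
            f"{max_resample_rate:.0%}; check psa_distributions"
        )
    result = PSAResult(delta_cost=delta_cost, delta_qaly=delta_qaly, n=n,
                       seed=seed, comparator=comparator_name,
                       resample_count=resamples)
    result.ceac = {w: result.ceac_at(w) for w in wtp_grid}
    return result


def one_way(
    scenario: Scenario,
    parameter: str,
    low: float,
    high: float,
    n_points: int = 11,
    comparator: int | str = 1,
) -> pd.DataFrame:
    """Deterministic sweep of one parameter; all else held at base case.

    Returns a frame with columns value, delta_cost, delta_qaly (discounted,
    intervention minus comparator).
    """
    if not low < high:
        raise ValueError("low must be strictly below high")
    get_param(scenario, parameter)
    values = np.linspace(low, high, n_points)
    rows = []
    for v in values:
        scn = with_param(scenario, parameter, float(v))
        a, b = _incremental(scn, comparator)
        rows.append({
            "value": float(v),
            "delta_cost": a.total_cost - b.total_cost,
            "delta_qaly": a.total_qaly - b.total_qaly,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """Parameter value at which incremental discounted cost crosses zero."""

    parameter: str
    threshold_value: float
    direction: str  # strategy that becomes the less expensive beyond the threshold
    delta_cost_at_threshold: float


def find_threshold(
    scenario: Scenario,
    parameter: str,
    low: float,
    high: float,
    tol: float = 1e-6,
    comparator: int | str = 1,
) -> ThresholdResult:
    """Bisection root of incremental discounted cost over a parameter interval.

    Raises ValueError("no threshold in range") when the incremental cost does
    not change sign on [low, high].
    """
    get_param(scenario, parameter)

    def f(v: float) -> float:
        a, b = _incremental(with_param(scenario, parameter, float(v)), comparator)
        return a.total_cost - b.total_cost

    f_low, f_high = f(low), f(high)
    if f_low == 0.0:
        root, f_root = low, f_low
    elif f_high == 0.0:
        root, f_root = high, f_high
    elif np.sign(f_low) == np.sign(f_high):
        raise ValueError(
            f"no threshold in range: incremental cost is "
            f"{f_low:+.2f} at {low} and {f_high:+.2f} at {high}"
        )
    else:
        root = float(brentq(f, low, high, xtol=1e-12, rtol=1e-14))
        f_root = f(root)
    if abs(f_root) > tol:
        raise RuntimeError(
            f"threshold root found at {root} but |delta cost| = {abs(f_root)} > tol"
        )
    intervention = scenario.strategies[0].name
    comparator_name = scenario.strategy(comparator).name
    direction = comparator_name if f_high > 0 else intervention
    return ThresholdResult(parameter=parameter, threshold_value=root,
                           direction=direction, delta_cost_at_threshold=f_root)


@dataclass
class TornadoResult:
    """One-way influence bars sorted by descending width."""

    entries: list[tuple[str, float, float, float, float]]
    # (parameter, low, high, outcome_at_low, outcome_at_high)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["parameter", "low", "high", "outcome_low", "outcome_high"],
        )


def tornado(
    scenario: Scenario,
    param_ranges: dict[str, tuple[float, float]],
    comparator: int | str = 1,
) -> TornadoResult:
    """One-way sensitivity of incremental discounted cost at range endpoints."""
    if not param_ranges:
        raise ValueError("param_ranges must be non-empty")
    entries = []
    for parameter, (low, high) in param_ranges.items():
        curve = one_way(scenario, parameter, low, high, n_points=2,
                        comparator=comparator)
        entries.append((
            parameter, float(low), float(high),
            float(curve.delta_cost.iloc[0]), float(curve.delta_cost.iloc[1]),
        ))
    entries.sort(key=lambda e: -abs(e[4] - e[3]))
    return TornadoResult(entries=entries)


def default_tornado_ranges(
    scenario: Scenario, relative: float = 0.25
) -> dict[str, tuple[float, float]]:
    """+-25% ranges over all dropout, relapse, retreatment, effect and cost
    parameters (probabilities clipped to [0, 0.99])."""
    ranges: dict[str, tuple[float, float]] = {}
    swept_fields = _PROB_FIELDS + ("effect_mean", "per_course_cost", "annual_drug_cost")
    for s in scenario.strategies:
        for fname in swept_fields:
            base = float(getattr(s, fname))
            if base == 0:
                continue
            lo, hi = base * (1 - relative), base * (1 + relative)
            if fname in _PROB_FIELDS:
                lo, hi = max(lo, 0.0), min(hi, 0.99)
            ranges[f"strategies.{s.name}.{fname}"] = (lo, hi)
    for band, cost in scenario.state_costs.quarterly_cost_by_band.items():
        if cost > 0:
            ranges[f"state_costs.{band}"] = (cost * (1 - relative),
                                             cost * (1 + relative))
    return ranges
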