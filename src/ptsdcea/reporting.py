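"""Run orchestration and report assembly for one scenario comparison."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import sensitivity
from .engine import RunResult, run_strategy
from .outcomes import IncrementalResult, compare
from .scenario import Scenario


@dataclass
class ComparisonReport:
    """Everything the base case, PSA and threshold analyses report for one
    intervention/comparator pair."""

    scenario: str
    intervention: str
    comparator: str
    yearly_cost_difference: dict[int, float]   # cumulative discounted, int - comp
    yearly_savings: dict[int, float]           # comparator minus intervention
    total_qaly_difference: float
    incremental: IncrementalResult
    psa_n: int = 0
    psa_seed: int = 0
    fraction_dominant: float | None = None
    fraction_cheaper: float | None = None
    fraction_dominated: float | None = None
    thresholds: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "intervention": self.intervention,
            "comparator": self.comparator,
            "yearly_cost_difference": {str(k): v for k, v
                                       in self.yearly_cost_difference.items()},
            "yearly_savings": {str(k): v for k, v in self.yearly_savings.items()},
            "total_qaly_difference": self.total_qaly_difference,
            "incremental": self.incremental.to_dict(),
            "psa": {
                "n": self.psa_n,
                "seed": self.psa_seed,
                "fraction_dominant": self.fraction_dominant,
                "fraction_cheaper": self.fraction_cheaper,
                "fraction_dominated": self.fraction_dominated,
            },
            "thresholds": self.thresholds,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def base_case_runs(
    scenario: Scenario, comparator: int | str = 1
) -> tuple[RunResult, RunResult]:
    _, a = run_strategy(scenario, 0)
    _, b = run_strategy(scenario, comparator)
    return a, b


def build_report(
    scenario: Scenario,
    comparator: int | str = 1,
    psa_n: int = 10_000,
    seed: int | None = None,
    wtp: float | None = None,
    threshold_params: list[str] | None = None,
    threshold_range: tuple[float, float] = (0.01, 0.6),
) -> ComparisonReport:
    """Base case + PSA + dropout thresholds for one comparison.

    ``threshold_params`` defaults to the dropout probability of both
    strategies; parameters whose incremental cost never changes sign on the
    searched range are reported with a null threshold.
    """
    if seed is None:
        seed = scenario.seed
    if wtp is None:
        wtp = scenario.wtp_per_qaly
    a, b = base_case_runs(scenario, comparator)
    inc = compare(a, b, wtp=wtp)
    cum_a, cum_b = a.cumulative_by_year(), b.cumulative_by_year()
    yearly_diff = {y: cum_a[y][0] - cum_b[y][0] for y in cum_a}
    report = ComparisonReport(
        scenario=scenario.name,
        intervention=a.strategy_name,
        comparator=b.strategy_name,
        yearly_cost_difference=yearly_diff,
        yearly_savings={y: -d for y, d in yearly_diff.items()},
        total_qaly_difference=inc.delta_qaly,
        incremental=inc,
    )
    if psa_n > 0 and scenario.psa_distributions:
        psa = sensitivity.run_psa(scenario, n=psa_n, seed=seed,
                                  comparator=comparator)
        report.psa_n = psa.n
        report.psa_seed = psa.seed
        report.fraction_dominant = psa.fraction_dominant
        report.fraction_cheaper = psa.fraction_cheaper
        report.fraction_dominated = psa.fraction_dominated
    if threshold_params is None:
        threshold_params = [
            f"strategies.{scenario.strategies[0].name}.dropout_course_prob",
            f"strategies.{scenario.strategy(comparator).name}.dropout_course_prob",
        ]
    for param in threshold_params:
        lo, hi = threshold_range
        try:
            th = sensitivity.find_threshold(scenario, param, lo, hi,
                                            comparator=comparator)
            report.thresholds.append({
                "parameter": th.parameter,
                "threshold_value": th.threshold_value,
                "direction": th.direction,
            })
        except ValueError:
            report.thresholds.append({
                "parameter": param, "threshold_value": None, "direction": None,
            })
    return report
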