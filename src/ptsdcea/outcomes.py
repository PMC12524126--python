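"""Mapping clinical severity to utilities and comparing strategies.

CAPS-5 (Clinician-Administered PTSD Scale for DSM-5, 0-80, lower is better)
is mapped linearly to EQ-VAS (EuroQol visual analogue scale, 0-100, higher is
better); EQ-VAS / 100 is the utility weight used for QALY accrual.  The module
also classifies incremental cost/effect pairs on the cost-effectiveness plane
and reweights pooled treatment effects across patient subgroups (e.g. a
military/civilian mix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from pydantic import BaseModel, ConfigDict, field_validator

if TYPE_CHECKING:  # pragma: no cover
    from .scenario import SeverityBand

CAPS5_MIN = 0.0
CAPS5_MAX = 80.0

#: Cost-effectiveness plane quadrant labels (intervention minus comparator).
DOMINANT = "dominant"          # cheaper and more effective
DOMINATED = "dominated"        # costlier and less effective
TRADE_OFF_NE = "trade_off_ne"  # costlier and more effective
TRADE_OFF_SW = "trade_off_sw"  # cheaper and less effective


class RegressionMap(BaseModel):
    """Linear CAPS-5 -> EQ-VAS map; predictions are clamped to [0, 100]."""

    model_config = ConfigDict(extra="forbid")

    intercept: float
    slope: float

    @field_validator("slope")
    @classmethod
    def _slope_negative(cls, v: float) -> float:
        if v >= 0:
            raise ValueError("slope must be negative: higher CAPS-5 means worse health")
        return v


def caps5_to_eqvas(reg: RegressionMap, caps5: float) -> float:
    """Predicted EQ-VAS for a CAPS-5 score, clamped to the 0-100 scale."""
    if not CAPS5_MIN <= caps5 <= CAPS5_MAX:
        raise ValueError(
            f"CAPS-5 score {caps5} outside instrument range [{CAPS5_MIN:g}, {CAPS5_MAX:g}]"
        )
    return min(100.0, max(0.0, reg.intercept + reg.slope * caps5))


def band_utility(reg: RegressionMap, band: "SeverityBand") -> float:
    """Utility weight of a severity band: EQ-VAS at the band midpoint / 100."""
    midpoint = (band.caps5_low + band.caps5_high) / 2.0
    return caps5_to_eqvas(reg, midpoint) / 100.0


def classify_quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Quadrant of an (incremental cost, incremental QALY) pair.

    Boundary convention: a draw with delta_qaly == 0 is never "dominant" or
    "dominated"; (0, 0) classifies as trade_off_ne.
    """
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    if delta_cost >= 0 and delta_qaly >= 0:
        return TRADE_OFF_NE
    return TRADE_OFF_SW


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost-effectiveness of an intervention against a comparator.

    ``icer`` is None (undefined) when the QALY difference is exactly zero.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str

    def net_monetary_benefit(self, wtp: float) -> float:
        """wtp * delta_qaly - delta_cost; positive favours the intervention."""
        return wtp * self.delta_qaly - self.delta_cost

    def preferred(self, wtp: float = 0.0) -> str:
        """"intervention" or "comparator" under a willingness-to-pay threshold.

        At wtp = 0 this reduces to cost minimisation.
        """
        return "intervention" if self.net_monetary_benefit(wtp) > 0 else "comparator"

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare(a, b, wtp: float = 0.0) -> IncrementalResult:
    """Incremental result of run ``a`` (intervention) against ``b`` (comparator).

    Both arguments are RunResult-like objects exposing discounted
    ``total_cost`` / ``total_qaly``; horizons must match.
    """
    if getattr(a, "n_cycles", None) != getattr(b, "n_cycles", None):
        raise ValueError("cannot compare runs with different horizons")
    delta_cost = a.total_cost - b.total_cost
    delta_qaly = a.total_qaly - b.total_qaly
    icer = None if delta_qaly == 0 else delta_cost / delta_qaly
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        classification=classify_quadrant(delta_cost, delta_qaly),
    )


def _check_mix(mix: Mapping[str, float], name: str) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total}, expected 1")


def normalize_effect(
    effect_by_subgroup: Mapping[str, float],
    source_mix: Mapping[str, float],
    target_mix: Mapping[str, float],
) -> float:
    """Reweight subgroup-specific effects from a source to a target population mix.

    Returns sum(target_mix[g] * effect_by_subgroup[g]).  The source mix is
    validated against the same subgroup keys so that callers pass the mix the
    effects were pooled under; when source and target mixes are equal the
    pooled effect is returned unchanged.
    """
    keys = set(effect_by_subgroup)
    if set(source_mix) != keys or set(target_mix) != keys:
        raise ValueError(
            "subgroup keys differ between effects and mixes: "
            f"{sorted(keys)} vs {sorted(source_mix)} vs {sorted(target_mix)}"
        )
    _check_mix(source_mix, "source_mix")
    _check_mix(target_mix, "target_mix")
    return sum(target_mix[g] * effect_by_subgroup[g] for g in keys)


def solve_subgroup_effects(
    pooled_mean: float,
    source_mix: Mapping[str, float],
    effect_ratio: float,
    numerator: str,
    denominator: str,
) -> dict[str, float]:
    """Split a pooled two-subgroup effect given the effect ratio between them.

    ``effect_ratio`` is effect(numerator) / effect(denominator).  Solves
    pooled = w_n * r * e_d + w_d * e_d for e_d.
    """
    if set(source_mix) != {numerator, denominator}:
        raise ValueError("source_mix keys must be exactly the two subgroups")
    _check_mix(source_mix, "source_mix")
    w_n, w_d = source_mix[numerator], source_mix[denominator]
    denom = w_n * effect_ratio + w_d
    if denom <= 0:
        raise ValueError("infeasible mix/ratio combination")
    e_d = pooled_mean / denom
    return {numerator: effect_ratio * e_d, denominator: e_d}


def solve_effect_ratio(
    pooled_source: float,
    pooled_target: float,
    source_mix: Mapping[str, float],
    target_mix: Mapping[str, float],
    numerator: str,
    denominator: str,
) -> float:
    """Subgroup effect ratio implied by a pooled effect under two mixes.

    With two subgroups and a common per-subgroup effect, the pooled means under
    the source and target mixes pin down the ratio r = e_n / e_d:

        pooled_t / pooled_s = (w_t_n r + w_t_d) / (w_s_n r + w_s_d)
    """
    for mix in (source_mix, target_mix):
        if set(mix) != {numerator, denominator}:
            raise ValueError("mix keys must be exactly the two subgroups")
    _check_mix(source_mix, "source_mix")
    _check_mix(target_mix, "target_mix")
    ratio = pooled_target / pooled_source
    num = target_mix[denominator] - ratio * source_mix[denominator]
    den = ratio * source_mix[numerator] - target_mix[numerator]
    if den == 0:
        raise ValueError("mixes do not identify the effect ratio")
    r = num / den
    if r <= 0:
        raise ValueError(f"implied effect ratio {r:g} is not positive; check inputs")
    return r
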