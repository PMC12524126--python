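"""Model specification: severity bands, therapy profiles, costs, distributions.

A :class:`Scenario` is the single validated object the rest of the package
consumes.  Scenarios round-trip losslessly through YAML (``load_scenario`` /
``save_scenario``) and three base-case fixtures ship with the package:
``nf_vs_psychotherapy``, ``nf_vs_pharmacotherapy`` and ``prism_vs_each``.

Parameter uncertainty is expressed with :class:`DistributionSpec`: gamma for
positive quantities (costs), beta for probabilities, normal for CAPS-5 effect
estimates.  ``fit_distribution`` builds a spec from a (mean, dispersion) pair
by method of moments; a dispersion given as a 95% CI width is converted to an
SD by dividing by 3.92 (two-sided normal interval).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .outcomes import RegressionMap

BandLabel = Literal["severe", "moderate", "mild", "asymptomatic"]

#: Severity order, worst first; used to validate band layout and mortality.
SEVERITY_ORDER: tuple[str, ...] = ("severe", "moderate", "mild", "asymptomatic")

#: Full 95% CI width of a normal = 2 * 1.96 SD.
CI95_WIDTH_PER_SD = 3.92


class SeverityBand(BaseModel):
    """A contiguous CAPS-5 score range with a clinical severity label."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    label: BandLabel
    caps5_low: int = Field(ge=0, le=80)
    caps5_high: int = Field(ge=0, le=80)

    @model_validator(mode="after")
    def _ordered(self) -> "SeverityBand":
        if self.caps5_low > self.caps5_high:
            raise ValueError(f"band {self.label}: caps5_low > caps5_high")
        return self

    @property
    def width(self) -> float:
        return float(self.caps5_high - self.caps5_low)

    @property
    def midpoint(self) -> float:
        return (self.caps5_low + self.caps5_high) / 2.0


DEFAULT_BANDS: tuple[SeverityBand, ...] = (
    SeverityBand(label="severe", caps5_low=60, caps5_high=80),
    SeverityBand(label="moderate", caps5_low=40, caps5_high=59),
    SeverityBand(label="mild", caps5_low=20, caps5_high=39),
    SeverityBand(label="asymptomatic", caps5_low=0, caps5_high=19),
)


class TherapyProfile(BaseModel):
    """One treatment strategy: costs, schedule, adherence and effect.

    ``dropout_course_prob`` and ``relapse_prob`` are the probabilities over
    their natural reporting period; ``course_cycles`` / ``relapse_cycles``
    state how many model cycles that period spans (1 = already per quarterly
    cycle).  ``effect_mean``/``effect_dispersion`` describe the CAPS-5 point
    reduction per course; a ``ci95`` dispersion is the full interval width.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    per_session_cost: float = Field(ge=0)
    sessions_per_course: float = Field(ge=0)
    per_course_cost: float = Field(ge=0)
    annual_drug_cost: float = Field(default=0.0, ge=0)
    course_cycles: int = Field(default=1, ge=1)
    dropout_course_prob: float = Field(ge=0, le=1)
    relapse_prob: float = Field(ge=0, le=1)
    relapse_cycles: int = Field(default=1, ge=1)
    retreatment_prob: float = Field(ge=0, le=1)
    effect_mean: float
    effect_dispersion: float = Field(ge=0)
    effect_dispersion_kind: Literal["sd", "ci95"] = "sd"

    @model_validator(mode="after")
    def _course_cost_consistent(self) -> "TherapyProfile":
        if self.per_session_cost > 0 and self.sessions_per_course > 0:
            implied = self.per_session_cost * self.sessions_per_course
            if abs(implied - self.per_course_cost) > 0.5:
                raise ValueError(
                    f"strategy {self.name}: per_course_cost {self.per_course_cost} "
                    f"differs from per_session_cost x sessions_per_course = {implied} "
                    "by more than 0.5 USD"
                )
        return self

    @property
    def effect_sd(self) -> float:
        """Effect SD in CAPS-5 points, converting a ci95 width if needed."""
        if self.effect_dispersion_kind == "ci95":
            return self.effect_dispersion / CI95_WIDTH_PER_SD
        return self.effect_dispersion


class StateCostTable(BaseModel):
    """Quarterly non-therapy care cost by severity band (USD)."""

    model_config = ConfigDict(extra="forbid")

    quarterly_cost_by_band: dict[BandLabel, float]

    @field_validator("quarterly_cost_by_band")
    @classmethod
    def _non_negative(cls, v: dict) -> dict:
        for band, cost in v.items():
            if cost < 0:
                raise ValueError(f"state cost for {band} is negative")
        return v

    def cost(self, band: str) -> float:
        return self.quarterly_cost_by_band.get(band, 0.0)


class MortalityTable(BaseModel):
    """Per-cycle (quarterly) death probability by severity band."""

    model_config = ConfigDict(extra="forbid")

    quarterly_death_prob_by_band: dict[BandLabel, float]

    @model_validator(mode="after")
    def _valid(self) -> "MortalityTable":
        probs = self.quarterly_death_prob_by_band
        for band, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"death probability for {band} outside [0, 1]")
        # worse bands must not have lower mortality
        present = [b for b in SEVERITY_ORDER if b in probs]
        for worse, better in zip(present, present[1:]):
            if probs[worse] < probs[better]:
                raise ValueError(
                    f"death probability non-monotone: {worse} < {better}"
                )
        return self

    def prob(self, band: str) -> float:
        return self.quarterly_death_prob_by_band.get(band, 0.0)


class DistributionSpec(BaseModel):
    """A sampling distribution for one uncertain parameter.

    Families: ``gamma`` (shape ``param_a``, scale ``param_b``), ``beta``
    (``param_a`` = alpha, ``param_b`` = beta), ``normal`` (mean, SD) and
    ``fixed`` (point mass at ``param_a``).  If only ``derived_from``
    [mean, sd] is given, parameters are filled in by method of moments.
    """

    model_config = ConfigDict(extra="forbid")

    family: Literal["gamma", "beta", "normal", "fixed"]
    param_a: Optional[float] = None
    param_b: Optional[float] = None
    derived_from: Optional[list[float]] = None

    @model_validator(mode="after")
    def _resolve(self) -> "DistributionSpec":
        if self.param_a is None:
            if self.derived_from is None or len(self.derived_from) != 2:
                raise ValueError(
                    "either explicit parameters or derived_from [mean, sd] required"
                )
            mean, sd = self.derived_from
            a, b = _moments_to_params(mean, sd, self.family)
            object.__setattr__(self, "param_a", a)
            object.__setattr__(self, "param_b", b)
        if self.family in ("gamma", "beta"):
            if self.param_a <= 0 or (self.param_b is None or self.param_b <= 0):
                raise ValueError(f"{self.family} parameters must be positive")
        if self.family == "normal" and (self.param_b is None or self.param_b < 0):
            raise ValueError("normal SD must be non-negative")
        return self

    def mean(self) -> float:
        if self.family == "gamma":
            return self.param_a * self.param_b
        if self.family == "beta":
            return self.param_a / (self.param_a + self.param_b)
        return self.param_a

    def sd(self) -> float:
        if self.family == "gamma":
            return math.sqrt(self.param_a) * self.param_b
        if self.family == "beta":
            a, b = self.param_a, self.param_b
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "normal":
            return self.param_b
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "gamma":
            return rng.gamma(self.param_a, self.param_b, size=size)
        if self.family == "beta":
            return rng.beta(self.param_a, self.param_b, size=size)
        if self.family == "normal":
            return rng.normal(self.param_a, self.param_b, size=size)
        return self.param_a if size is None else np.full(size, self.param_a)


def _moments_to_params(mean: float, sd: float, family: str) -> tuple[float, float]:
    if family == "fixed":
        return mean, 0.0
    if sd <= 0:
        raise ValueError("dispersion must be positive")
    if family == "normal":
        return mean, sd
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be positive")
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return shape, scale
    if family == "beta":
        if not 0 < mean < 1:
            raise ValueError("beta mean must lie strictly inside (0, 1)")
        if mean * (1 - mean) <= sd * sd:
            raise ValueError(
                f"beta moments infeasible: need sd^2 < mean(1-mean) "
                f"= {mean * (1 - mean):g}, got sd^2 = {sd * sd:g}"
            )
        nu = mean * (1 - mean) / (sd * sd) - 1
        return mean * nu, (1 - mean) * nu
    raise ValueError(f"unknown family {family!r}")


def fit_distribution(
    mean: float,
    dispersion: float,
    kind: Literal["sd", "ci95"] = "sd",
    family: Literal["gamma", "beta", "normal"] = "normal",
) -> DistributionSpec:
    """Method-of-moments distribution from a printed (mean, dispersion) pair.

    ``kind="ci95"`` interprets ``dispersion`` as the full width of a 95%
    confidence interval (SD = width / 3.92).
    """
    sd = dispersion / CI95_WIDTH_PER_SD if kind == "ci95" else dispersion
    a, b = _moments_to_params(mean, sd, family)
    return DistributionSpec(
        family=family, param_a=a, param_b=b, derived_from=[mean, sd]
    )


class Scenario(BaseModel):
    """Complete specification of one cost-effectiveness comparison.

    ``strategies[0]`` is the intervention; every later entry is a comparator.
    ``psa_distributions`` maps dotted parameter paths (see
    :mod:`ptsdcea.sensitivity`) to sampling distributions for probabilistic
    sensitivity analysis.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    strategies: list[TherapyProfile] = Field(min_length=2)
    bands: list[SeverityBand] = Field(default_factory=lambda: list(DEFAULT_BANDS))
    state_costs: StateCostTable
    mortality: MortalityTable
    initial_distribution: dict[BandLabel, float]
    horizon_cycles: int = Field(default=12, ge=1)
    cycle_length_years: float = Field(default=0.25, gt=0)
    annual_discount_rate: float = Field(default=0.03, ge=0)
    wtp_per_qaly: float = 0.0
    regression: RegressionMap = Field(
        default_factory=lambda: RegressionMap(intercept=92.0, slope=-0.68)
    )
    psa_distributions: dict[str, DistributionSpec] = Field(default_factory=dict)
    half_cycle: bool = False
    therapy_billing: Literal["every_cycle", "first_course"] = "every_cycle"
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "Scenario":
        labels = [b.label for b in self.bands]
        if sorted(labels) != sorted(set(labels)):
            raise ValueError("duplicate band labels")
        if set(labels) != set(SEVERITY_ORDER):
            raise ValueError(f"bands must cover exactly {SEVERITY_ORDER}")
        by_label = {b.label: b for b in self.bands}
        # disjoint and ordered by severity: asymptomatic < mild < moderate < severe
        ordered = [by_label[lbl] for lbl in reversed(SEVERITY_ORDER)]
        for lower, upper in zip(ordered, ordered[1:]):
            if lower.caps5_high >= upper.caps5_low:
                raise ValueError(
                    f"bands {lower.label} and {upper.label} overlap or are out of order"
                )
        names = [s.name for s in self.strategies]
        if len(names) != len(set(names)):
            raise ValueError("strategy names must be unique")
        total = sum(self.initial_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial_distribution sums to {total}, expected 1")
        for band, p in self.initial_distribution.items():
            if not 0 <= p <= 1:
                raise ValueError(f"initial proportion for {band} outside [0, 1]")
        return self

    # -- convenience accessors -------------------------------------------------

    @property
    def horizon_years(self) -> float:
        return self.horizon_cycles * self.cycle_length_years

    def band(self, label: str) -> SeverityBand:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    def symptomatic_bands(self) -> list[SeverityBand]:
        """Bands above asymptomatic, ordered worst (severe) first."""
        return sorted(
            (b for b in self.bands if b.label != "asymptomatic"),
            key=lambda b: -b.caps5_low,
        )

    def strategy(self, key: int | str) -> TherapyProfile:
        if isinstance(key, int):
            return self.strategies[key]
        for s in self.strategies:
            if s.name == key:
                return s
        raise KeyError(f"no strategy named {key!r}")


def load_scenario(path: str | Path) -> Scenario:
    """Read and validate a scenario YAML file; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return Scenario.model_validate(raw)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as YAML in canonical (declaration) key order."""
    data = scenario.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


FIXTURE_NAMES = ("nf_vs_psychotherapy", "nf_vs_pharmacotherapy", "prism_vs_each")


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped base-case scenario fixture."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(resources.files("ptsdcea").joinpath(f"fixtures/{name}.yaml"))


def load_fixture(name: str) -> Scenario:
    return load_scenario(fixture_path(name))
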