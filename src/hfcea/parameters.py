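"""Model inputs for the heart-failure diagnostic-imaging economic models.

This module defines the validated parameter set for the payer-perspective
Markov cohort model (disease states, strategies, transition inputs, cost and
utility schedules, discounting, cohort composition) and for the one-year
hospital contribution-margin model, together with the YAML configuration
loader.

The disease process is the ACCF/AHA heart-failure staging: Stage B
(structural disease, asymptomatic), Stage C (symptomatic), Stage C+
(post-hospitalization symptomatic), Stage D (refractory), and death. The
model is progressive: living patients either remain in their stage, advance
to the next-worse stage, or die.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

__all__ = [
    "DiseaseState",
    "STATES",
    "LIVING_STATES",
    "Strategy",
    "TransitionInputs",
    "TransitionMatrix",
    "StateCostSchedule",
    "UtilitySchedule",
    "DiscountSpec",
    "BackgroundMortality",
    "CohortSpec",
    "DetectionSpec",
    "EngineSettings",
    "ParamRange",
    "SensitivitySpec",
    "HospitalStrategyInputs",
    "OwnershipCost",
    "HospitalInputs",
    "ModelConfig",
    "ConfigError",
    "MatrixError",
    "InfeasibleRowError",
    "ReducedRate",
    "load_config",
    "save_config",
    "default_config",
    "default_config_path",
    "build_transition_matrix",
    "apply_hospitalization_reduction",
    "annualize_probability",
]

ROW_SUM_TOL = 1e-12


class ConfigError(Exception):
    """A configuration file violated the schema or a model invariant.

    Deliberately not a ValueError subclass: pydantic converts ValueErrors
    raised inside validators into ValidationError, whereas matrix errors
    should surface as themselves, naming the offending row.
    """


class MatrixError(ConfigError):
    """A transition matrix violated row-stochasticity or structure."""


class InfeasibleRowError(MatrixError):
    """Progression + death probabilities over-allocate a matrix row."""


class DiseaseState(str, enum.Enum):
    """The five Markov states, ordered by increasing severity."""

    STAGE_B = "StageB"
    STAGE_C = "StageC"
    STAGE_C_PLUS = "StageCplus"
    STAGE_D = "StageD"
    DEAD = "Dead"

    @property
    def severity(self) -> int:
        return STATES.index(self)


STATES: list[DiseaseState] = [
    DiseaseState.STAGE_B,
    DiseaseState.STAGE_C,
    DiseaseState.STAGE_C_PLUS,
    DiseaseState.STAGE_D,
    DiseaseState.DEAD,
]
LIVING_STATES: list[DiseaseState] = STATES[:-1]
N_STATES = len(STATES)
DEAD_INDEX = N_STATES - 1


class _Base(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return value


class Strategy(_Base):
    """A diagnostic-imaging strategy as seen by the payer model.

    ``test_cost`` is the payer's per-scan price (the reimbursed amount);
    ``test_reimbursement`` is kept separately for the hospital perspective.
    ``hospitalization_reduction`` is the relative reduction in the annual
    HF-hospitalization rate conferred by early diagnosis and treatment.
    """

    name: str
    diagnostic_accuracy: float = Field(ge=0.0, le=1.0)
    test_cost: float = Field(ge=0.0)
    test_reimbursement: float = Field(ge=0.0)
    contrast_cost: float = Field(ge=0.0, default=0.0)
    hospitalization_reduction: float = Field(ge=0.0, le=1.0, default=0.0)

    @property
    def annual_imaging_cost(self) -> float:
        """Payer cost of one annual scan, contrast included."""
        return self.test_cost + self.contrast_cost


class TransitionInputs(_Base):
    """Annual per-stage inputs from which a strategy's matrix is built."""

    stage_b_to_c: float = Field(ge=0.0, le=1.0)
    stage_c_to_cplus: float = Field(ge=0.0, le=1.0)
    stage_cplus_to_d: float = Field(ge=0.0, le=1.0)
    hf_mortality: float = Field(ge=0.0, le=1.0)

    @property
    def progression(self) -> dict[DiseaseState, float]:
        return {
            DiseaseState.STAGE_B: self.stage_b_to_c,
            DiseaseState.STAGE_C: self.stage_c_to_cplus,
            DiseaseState.STAGE_C_PLUS: self.stage_cplus_to_d,
            DiseaseState.STAGE_D: 0.0,
        }


class TransitionMatrix(_Base):
    """A validated 5x5 annual transition matrix over the disease states."""

    entries: list[list[float]]
    cycle_length: float = 1.0

    @field_validator("entries")
    @classmethod
    def _validate_entries(cls, entries: list[list[float]]) -> list[list[float]]:
        arr = np.asarray(entries, dtype=float)
        if arr.shape != (N_STATES, N_STATES):
            raise MatrixError(f"matrix must be {N_STATES}x{N_STATES}, got {arr.shape}")
        if np.any(arr < -ROW_SUM_TOL) or np.any(arr > 1 + ROW_SUM_TOL):
            raise MatrixError("matrix entries must be probabilities in [0, 1]")
        sums = arr.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > 1e-10:
                raise MatrixError(
                    f"row {STATES[i].value} sums to {s!r}, expected 1"
                )
        dead = arr[DEAD_INDEX]
        if dead[DEAD_INDEX] != 1.0 or dead[:DEAD_INDEX].any():
            raise MatrixError("Dead must be absorbing")
        # progressive structure: no transitions to less-severe living states
        for i in range(DEAD_INDEX):
            for j in range(i):
                if arr[i, j] != 0.0:
                    raise MatrixError(
                        f"backward transition {STATES[i].value}->{STATES[j].value} "
                        "not allowed in a progressive model"
                    )
        return entries

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.entries, dtype=float)


class StateCostSchedule(_Base):
    """Annual cost components attached to the disease states (USD).

    Drug costs are per member per month and are multiplied by 12 per cycle.
    Hospitalization enters Stage C+ as an expected cost: annual rate x mean
    cost x (1 + 30-day rehospitalization probability).
    """

    office_visit_cost: float = Field(ge=0.0)
    drug_cost_monthly: float = Field(ge=0.0)
    advanced_drug_cost_monthly: float = Field(ge=0.0)
    hf_hospitalization_prob: float = Field(ge=0.0, le=1.0)
    hf_hospitalization_cost: float = Field(ge=0.0)
    rehospitalization_prob_30d: float = Field(ge=0.0, le=1.0)
    intervention_prob: float = Field(ge=0.0, le=1.0)
    intervention_cost: float = Field(ge=0.0)
    palliative_cost: float = Field(ge=0.0)
    assist_device_prob: float = Field(ge=0.0, le=1.0)
    assist_device_cost: float = Field(ge=0.0)


class UtilitySchedule(_Base):
    """Health-state utilities in [0, 1]; Dead is fixed at 0."""

    StageB: float = Field(ge=0.0, le=1.0)
    StageC: float = Field(ge=0.0, le=1.0)
    StageCplus: float = Field(ge=0.0, le=1.0)
    StageD: float = Field(ge=0.0, le=1.0)
    Dead: float = 0.0

    @field_validator("Dead")
    @classmethod
    def _dead_zero(cls, v: float) -> float:
        if v != 0.0:
            raise ValueError("utility of Dead must be 0")
        return v

    def vector(self) -> np.ndarray:
        return np.array(
            [self.StageB, self.StageC, self.StageCplus, self.StageD, self.Dead]
        )

    def of(self, state: DiseaseState) -> float:
        return float(getattr(self, state.value))


class DiscountSpec(_Base):
    """Annual discount rates; the first accrued cycle is undiscounted."""

    rate_costs: float = Field(ge=0.0, default=0.03)
    rate_outcomes: float = Field(ge=0.0, default=0.03)
    convention: Literal["first_cycle_undiscounted"] = "first_cycle_undiscounted"


class BackgroundMortality(_Base):
    """Age-indexed annual probability of death from non-HF causes.

    A coarse grid with linear interpolation; clamped at the boundary values.
    The shipped table is a smooth Gompertz-style approximation, not an
    official life table.
    """

    ages: list[float]
    probs: list[float]

    @model_validator(mode="after")
    def _validate(self) -> "BackgroundMortality":
        if len(self.ages) != len(self.probs) or len(self.ages) < 2:
            raise ValueError("ages and probs must have equal length >= 2")
        if sorted(self.ages) != list(self.ages):
            raise ValueError("ages must be increasing")
        for p in self.probs:
            _check_prob("background mortality", p)
        return self

    def at(self, age: float) -> float:
        return float(np.interp(age, self.ages, self.probs))


class CohortSpec(_Base):
    """Composition of the screened cohort entering the model.

    ``hf_pretest_prevalence`` is the pre-test probability of Stage B+ heart
    failure after comorbidity screening; ``hf_stage_split`` divides that HF
    fraction across Stage B / C / C+ at entry (patients with a prior HF
    hospitalization enter beyond Stage B). The remainder of the cohort is
    "suspected" — screened but without HF — and converts to true Stage B at
    the annualized multi-year progression rate.
    """

    mean_age: float = Field(gt=0.0)
    max_age: float = 110.0
    hf_pretest_prevalence: float = Field(ge=0.0, le=1.0)
    hf_stage_split: list[float] = Field(default=[0.5, 0.25, 0.25])
    stageB_4yr_progression: float = Field(ge=0.0, lt=1.0)
    background_mortality: BackgroundMortality

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        if len(self.hf_stage_split) != 3:
            raise ValueError("hf_stage_split must have 3 entries (B, C, C+)")
        for p in self.hf_stage_split:
            _check_prob("hf_stage_split", p)
        if abs(sum(self.hf_stage_split) - 1.0) > 1e-9:
            raise ValueError("hf_stage_split must sum to 1")
        if self.max_age <= self.mean_age:
            raise ValueError("max_age must exceed mean_age")
        return self

    @property
    def annual_stageB_incidence(self) -> float:
        """Annual Stage-B conversion rate for the suspected fraction."""
        return annualize_probability(self.stageB_4yr_progression, 4)

    def start_distribution(self) -> np.ndarray:
        """Start occupancy over the five public disease states."""
        prev = self.hf_pretest_prevalence
        b, c, cp = self.hf_stage_split
        return np.array([1 - prev + prev * b, prev * c, prev * cp, 0.0, 0.0])


class DetectionSpec(_Base):
    """Stage-B detection substructure (the short-term diagnostic model).

    When enabled, Stage B is tracked in three compartments: suspected
    (no HF yet; screening cost only; background mortality only), detected
    (diagnosed early HF under outpatient management), and undetected
    (missed early HF, incurring acute HF-hospitalization costs until
    diagnosed). Undetected patients are found either by the annual repeat
    scan (with the strategy's diagnostic accuracy) or following an HF
    hospitalization event.
    """

    enabled: bool = True
    post_hosp_diagnosis_rate: float = Field(ge=0.0, le=1.0, default=0.5)
    annual_rescreening: bool = True


class EngineSettings(_Base):
    stop_epsilon: float = Field(gt=0.0, lt=1.0, default=1e-9)
    max_cycles: int = Field(ge=1, default=100)
    cost_weighting: Literal["stay_probability", "occupancy"] = "stay_probability"
    qaly_mode: Literal["state_specific", "cohort_average"] = "state_specific"
    half_cycle_correction: bool = False
    apply_background_mortality: bool = True
    stage_b_hf_mortality: bool = True


class ParamRange(_Base):
    """A one-way sensitivity range around a config parameter."""

    path: str
    low: float
    high: float
    base: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "ParamRange":
        if self.low > self.high:
            raise ValueError(f"range for {self.path}: low > high")
        if self.base is not None and not (self.low <= self.base <= self.high):
            raise ValueError(f"range for {self.path}: base outside [low, high]")
        return self


class SensitivitySpec(_Base):
    wtp: float = Field(gt=0.0, default=50_000.0)
    outcome: Literal["cost_per_qaly", "icer"] = "cost_per_qaly"
    ranges: list[ParamRange] = Field(default_factory=list)


class OwnershipCost(_Base):
    """Equipment ownership amortized to a per-test fee."""

    acquisition: float = Field(ge=0.0)
    annual_maintenance: float = Field(ge=0.0)
    equipment_lifetime: float = Field(ge=1.0)
    amortization_population: int = Field(ge=0)


class HospitalStrategyInputs(_Base):
    """Per-strategy inputs of the hospital contribution-margin model."""

    test_reimbursement: float = Field(ge=0.0)
    contrast_reimbursement: float = Field(ge=0.0, default=0.0)
    facility_cost_per_hour: float = Field(ge=0.0)
    machine_minutes: float = Field(gt=0.0)
    contrast_cost: float = Field(ge=0.0, default=0.0)
    reading_fee: float = Field(ge=0.0, default=0.0)
    test_inventory_cost: float = Field(ge=0.0, default=0.0)
    diagnostic_accuracy: float = Field(ge=0.0, le=1.0)
    per_visit_cost_override: Optional[float] = Field(ge=0.0, default=None)
    ownership: Optional[OwnershipCost] = None


class HospitalInputs(_Base):
    annual_imaged_population: int = Field(ge=0)
    hf_prevalence: float = Field(ge=0.0, le=1.0)
    followup_scans_per_identified_patient: float = Field(ge=0.0)
    hosp_reimbursement: float = Field(ge=0.0)
    hosp_cost: float = Field(ge=0.0)
    rehosp_30d_prob: float = Field(ge=0.0, le=1.0)
    procedure_rates: dict[str, float] = Field(default_factory=dict)
    procedure_margins: dict[str, float] = Field(default_factory=dict)
    strategies: dict[str, HospitalStrategyInputs]

    @field_validator("procedure_rates")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            _check_prob(f"procedure rate {k}", p)
        return v


class ModelConfig(_Base):
    """The full parameter set for one payer-model comparison."""

    schema_version: int = 1
    comparator: str = "ECHO"
    intervention: str = "FastSENC"
    strategies: dict[str, Strategy]
    transitions: dict[str, TransitionInputs]
    costs: StateCostSchedule
    utilities: UtilitySchedule
    discount: DiscountSpec = Field(default_factory=DiscountSpec)
    cohort: CohortSpec
    detection: DetectionSpec = Field(default_factory=DetectionSpec)
    engine: EngineSettings = Field(default_factory=EngineSettings)
    sensitivity: SensitivitySpec = Field(default_factory=SensitivitySpec)
    hospital: Optional[HospitalInputs] = None

    @model_validator(mode="after")
    def _validate(self) -> "ModelConfig":
        if len(self.strategies) != 2:
            raise ValueError("exactly two strategies are required")
        for name in (self.comparator, self.intervention):
            if name not in self.strategies:
                raise ValueError(f"strategy {name!r} missing from strategies")
            if name not in self.transitions:
                raise ValueError(f"strategy {name!r} missing from transitions")
        for name, strat in self.strategies.items():
            if strat.name != name:
                raise ValueError(
                    f"strategy key {name!r} disagrees with name {strat.name!r}"
                )
        # every strategy matrix must be feasible with and without the
        # oldest-age background mortality folded in
        for name in self.strategies:
            for age in (self.cohort.mean_age, self.cohort.max_age):
                self.transition_matrix(name, age=age)
        return self

    def background_mortality_at(self, age: float) -> float:
        if not self.engine.apply_background_mortality:
            return 0.0
        return self.cohort.background_mortality.at(age)

    def transition_matrix(self, strategy: str, age: float | None = None) -> TransitionMatrix:
        """The strategy's 5-state matrix at a given age (default: entry age)."""
        if age is None:
            age = self.cohort.mean_age
        ti = self.transitions[strategy]
        return build_transition_matrix(
            ti.progression,
            ti.hf_mortality,
            self.background_mortality_at(age),
            stage_b_hf_mortality=self.engine.stage_b_hf_mortality,
        )


class ReducedRate(BaseModel):
    """An adjusted event rate together with the relative reduction applied."""

    rate: float
    relative_reduction: float


def combine_independent_risks(p1: float, p2: float) -> float:
    """Combine two competing annual death probabilities assuming independence."""
    return 1.0 - (1.0 - p1) * (1.0 - p2)


def build_transition_matrix(
    progression_probs: dict[DiseaseState, float],
    hf_mortality: float,
    background_mortality: float,
    stage_b_hf_mortality: bool = True,
) -> TransitionMatrix:
    """Assemble a progressive annual transition matrix.

    Each living state moves to the next-worse state with its progression
    probability, dies with probability 1 - (1 - hf_mortality) x
    (1 - background_mortality) (Stage B uses background mortality only when
    ``stage_b_hf_mortality`` is False), and otherwise stays. Raises
    :class:`InfeasibleRowError` if a row over-allocates.
    """
    _check_prob("hf_mortality", hf_mortality)
    _check_prob("background_mortality", background_mortality)
    arr = np.zeros((N_STATES, N_STATES))
    for i, state in enumerate(LIVING_STATES):
        prog = progression_probs.get(state, 0.0)
        _check_prob(f"progression from {state.value}", prog)
        if state is DiseaseState.STAGE_B and not stage_b_hf_mortality:
            death = background_mortality
        else:
            death = combine_independent_risks(hf_mortality, background_mortality)
        stay = 1.0 - prog - death
        if stay < -ROW_SUM_TOL:
            raise InfeasibleRowError(
                f"row {state.value}: progression {prog} + death {death} exceed 1"
            )
        stay = max(stay, 0.0)
        arr[i, i] = stay
        if prog > 0.0:
            arr[i, i + 1] += prog
        arr[i, DEAD_INDEX] = death
        # renormalize away float residue
        arr[i] /= arr[i].sum()
    arr[DEAD_INDEX, DEAD_INDEX] = 1.0
    return TransitionMatrix(entries=arr.tolist())


def apply_hospitalization_reduction(
    base_rate: float, preventable_fraction: float, capture_fraction: float
) -> ReducedRate:
    """Reduce an annual HF-hospitalization rate by the captured share of
    preventable admissions.

    The relative reduction is ``preventable_fraction x capture_fraction``
    (e.g. 54.2% preventable, half captured by early diagnosis -> 27.1%).
    """
    _check_prob("base_rate", base_rate)
    _check_prob("preventable_fraction", preventable_fraction)
    _check_prob("capture_fraction", capture_fraction)
    reduction = preventable_fraction * capture_fraction
    return ReducedRate(rate=base_rate * (1.0 - reduction), relative_reduction=reduction)


def annualize_probability(multi_year_prob: float, years: float) -> float:
    """Convert a multi-year cumulative probability to a constant annual one.

    Solves 1 - (1 - p_annual)^years = p_multi, i.e.
    p_annual = 1 - (1 - p_multi)^(1/years).
    """
    if not 0.0 <= multi_year_prob < 1.0:
        raise ValueError(
            f"multi-year probability must be in [0, 1), got {multi_year_prob}"
        )
    if years < 1:
        raise ValueError("years must be >= 1")
    return 1.0 - (1.0 - multi_year_prob) ** (1.0 / years)


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Raises :class:`ConfigError` naming the offending field on any schema or
    invariant violation (row-sum failures name the matrix row).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return ModelConfig.model_validate(raw)
    except MatrixError:
        raise
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the packaged default configuration."""
    return Path(resources.files("hfcea").joinpath("data/default_config.yaml"))


def default_config() -> ModelConfig:
    """The shipped base-case configuration (all printed model inputs)."""
    return load_config(default_config_path())
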