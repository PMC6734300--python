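"""Cohort propagation and discounted accumulation for the payer model.

The cohort is propagated through an annual-cycle Markov chain until (almost)
everyone has died or the maximum age is reached. Rewards — costs, life-years
and QALYs — accrue on the end-of-cycle occupancy: the summary for year t
reflects the deaths, hospitalizations and stage changes that happened during
that year. The first accrued cycle is undiscounted and cycle t is discounted
by (1 + r)^-(t-1).

When the Stage-B detection substructure is enabled (the default), the
engine expands Stage B into suspected / detected / undetected compartments;
the public cohort trace aggregates them back to the five disease states.

Costing follows the stated composition rule of the source model: per-state
costs are weighted by the probability of remaining in the state for the
cycle (``stay_probability`` mode); conventional occupancy weighting is
available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    DEAD_INDEX,
    LIVING_STATES,
    N_STATES,
    STATES,
    DiseaseState,
    ModelConfig,
    StateCostSchedule,
    Strategy,
    TransitionMatrix,
    apply_hospitalization_reduction,
)

__all__ = [
    "CohortTrace",
    "HorizonSummary",
    "AccumulationResult",
    "CompartmentModel",
    "HORIZON_YEARS",
    "run_cohort",
    "state_cycle_cost",
    "expected_cycle_cost",
    "discount_factor",
    "accumulate",
    "trace_frame",
]

HORIZON_YEARS = (1, 3, 5, 10)

# compartment labels when the detection substructure is enabled
_DETECT_LABELS = [
    "StageB_suspected",
    "StageB_detected",
    "StageB_undetected",
    "StageC",
    "StageCplus",
    "StageD",
    "Dead",
]
# map of each detection compartment onto the five public states
_DETECT_STATE_MAP = [0, 0, 0, 1, 2, 3, 4]


def state_cycle_cost(
    state: DiseaseState, costs: StateCostSchedule, strategy: Strategy
) -> float:
    """Annual cost attached to one disease state for one strategy (USD).

    Stage B: office visits + standard drugs + the strategy's annual scan.
    Stage C: visits + standard drugs + expected procedural intervention.
    Stage C+: advanced drugs + expected HF hospitalization (rate adjusted by
    the strategy's hospitalization reduction) including the 30-day
    rehospitalization expectation. Stage D: palliative care + expected
    assist-device implantation. Dead: 0.
    """
    if state is DiseaseState.DEAD:
        return 0.0
    if state is DiseaseState.STAGE_B:
        return (
            costs.office_visit_cost
            + 12.0 * costs.drug_cost_monthly
            + strategy.annual_imaging_cost
        )
    if state is DiseaseState.STAGE_C:
        return (
            costs.office_visit_cost
            + 12.0 * costs.drug_cost_monthly
            + costs.intervention_prob * costs.intervention_cost
        )
    if state is DiseaseState.STAGE_C_PLUS:
        hosp = costs.hf_hospitalization_prob * (1.0 - strategy.hospitalization_reduction)
        return (
            12.0 * costs.advanced_drug_cost_monthly
            + hosp
            * costs.hf_hospitalization_cost
            * (1.0 + costs.rehospitalization_prob_30d)
        )
    if state is DiseaseState.STAGE_D:
        return (
            costs.palliative_cost
            + costs.assist_device_prob * costs.assist_device_cost
        )
    raise ValueError(f"unknown disease state: {state!r}")


class CompartmentModel:
    """The (possibly detection-expanded) chain for one strategy.

    Provides the start vector, age-dependent transition matrix, and the
    per-compartment cost and utility vectors that the cohort engine and the
    individual-level simulator share.
    """

    def __init__(self, config: ModelConfig, strategy_name: str):
        self.config = config
        self.strategy = config.strategies[strategy_name]
        self.reference = config.strategies[config.comparator]
        self.own = config.transitions[strategy_name]
        self.ref = config.transitions[config.comparator]
        self.detection = config.detection.enabled
        if self.detection:
            self.labels = list(_DETECT_LABELS)
            self.state_map = np.array(_DETECT_STATE_MAP)
        else:
            self.labels = [s.value for s in STATES]
            self.state_map = np.arange(N_STATES)
        self.n = len(self.labels)
        self.dead_index = self.n - 1

    # -- structure -----------------------------------------------------

    def start_vector(self) -> np.ndarray:
        cohort = self.config.cohort
        start5 = cohort.start_distribution()
        if not self.detection:
            return start5
        prev = cohort.hf_pretest_prevalence
        b_split = cohort.hf_stage_split[0]
        acc = self.strategy.diagnostic_accuracy
        hf_b = prev * b_split
        v = np.zeros(self.n)
        v[0] = 1.0 - prev              # suspected, no HF yet
        v[1] = hf_b * acc              # early HF, found at initial screening
        v[2] = hf_b * (1.0 - acc)      # early HF, missed
        v[3] = start5[1]
        v[4] = start5[2]
        return v

    def _death(self, hf_mortality: float, age: float, stage_b: bool = False) -> float:
        bg = self.config.background_mortality_at(age)
        if stage_b and not self.config.engine.stage_b_hf_mortality:
            return bg
        return 1.0 - (1.0 - hf_mortality) * (1.0 - bg)

    def matrix(self, age: float) -> np.ndarray:
        """Annual transition matrix for a cohort member of the given age."""
        if not self.detection:
            return self.config.transition_matrix(self.strategy.name, age=age).array
        cfg = self.config
        n = self.n
        M = np.zeros((n, n))
        bg = cfg.background_mortality_at(age)
        inc = cfg.cohort.annual_stageB_incidence
        acc = self.strategy.diagnostic_accuracy
        # suspected: background mortality only; converts to Stage B HF,
        # split by the strategy's detection accuracy at the annual scan
        if bg + inc > 1.0:
            inc = 1.0 - bg
        M[0, 0] = 1.0 - bg - inc
        M[0, 1] = inc * acc
        M[0, 2] = inc * (1.0 - acc)
        M[0, 6] = bg
        # detected Stage B: the cohort's own (treated) rates
        p_own = self.own.stage_b_to_c
        d_own = self._death(self.own.hf_mortality, age, stage_b=True)
        self._fill_living(M, 1, stay_to=1, next_to=3, prog=p_own, death=d_own)
        # undetected Stage B: standard-care (comparator) rates; found via
        # annual rescreening or following an HF hospitalization event
        p_ref = self.ref.stage_b_to_c
        d_ref = self._death(self.ref.hf_mortality, age, stage_b=True)
        resid = 1.0 - p_ref - d_ref
        if resid < 0:
            raise ValueError("undetected Stage B row over-allocated")
        det = 0.0
        if cfg.detection.annual_rescreening:
            det += acc
        det += (
            cfg.detection.post_hosp_diagnosis_rate
            * cfg.costs.hf_hospitalization_prob
        )
        det = min(det, 1.0, resid)
        M[2, 1] = det
        M[2, 2] = resid - det
        M[2, 3] = p_ref
        M[2, 6] = d_ref
        d = self._death(self.own.hf_mortality, age)
        self._fill_living(M, 3, stay_to=3, next_to=4, prog=self.own.stage_c_to_cplus, death=d)
        self._fill_living(M, 4, stay_to=4, next_to=5, prog=self.own.stage_cplus_to_d, death=d)
        self._fill_living(M, 5, stay_to=5, next_to=None, prog=0.0, death=d)
        M[6, 6] = 1.0
        return M

    def _fill_living(self, M, i, stay_to, next_to, prog, death):
        stay = 1.0 - prog - death
        if stay < 0:
            raise ValueError(f"compartment row {self.labels[i]} over-allocated")
        M[i, stay_to] = stay
        if next_to is not None and prog > 0:
            M[i, next_to] = prog
        M[i, self.dead_index] = death

    # -- rewards -------------------------------------------------------

    def cost_vector(self) -> np.ndarray:
        costs = self.config.costs
        strat = self.strategy
        by_state = np.array(
            [state_cycle_cost(s, costs, strat) for s in STATES]
        )
        if not self.detection:
            return by_state
        v = by_state[self.state_map].astype(float)
        # suspected: the annual screening scan only (no HF, no HF care)
        v[0] = strat.annual_imaging_cost
        # undetected early HF: screening scan plus unmanaged acute
        # hospitalization expectation at the unreduced rate
        v[2] = strat.annual_imaging_cost + (
            costs.hf_hospitalization_prob
            * costs.hf_hospitalization_cost
            * (1.0 + costs.rehospitalization_prob_30d)
        )
        return v

    def utility_vector(self) -> np.ndarray:
        return self.config.utilities.vector()[self.state_map]

    def aggregate(self, comp_rows: np.ndarray) -> np.ndarray:
        """Collapse compartment occupancy rows onto the five public states."""
        out = np.zeros(comp_rows.shape[:-1] + (N_STATES,))
        for j, s in enumerate(self.state_map):
            out[..., s] += comp_rows[..., j]
        return out


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy for one strategy.

    ``occupancy`` holds the five public states (row 0 is the start
    distribution); ``compartments`` holds the engine's internal resolution,
    which coincides with ``occupancy`` when detection tracking is off.
    ``stay_probs[t-1]`` are the diagonal (stay) probabilities of the matrix
    applied during cycle t, used by the stay-probability costing rule.
    """

    strategy: str
    occupancy: np.ndarray
    compartments: np.ndarray
    compartment_labels: list[str]
    stay_probs: np.ndarray
    cycles_run: int
    converged: bool
    warning: str | None = None

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD_INDEX]


@dataclass
class HorizonSummary:
    """Cumulative discounted cost / LY / QALY at one reporting horizon."""

    horizon: str
    years: int
    cost: float
    undiscounted_cost: float
    life_years: float
    qalys: float
    truncated: bool = False


@dataclass
class AccumulationResult:
    strategy: str
    horizons: list[HorizonSummary]
    cycles: pd.DataFrame
    cost_weighting: str
    qaly_mode: str

    def at(self, horizon: str) -> HorizonSummary:
        for h in self.horizons:
            if h.horizon == horizon:
                return h
        raise KeyError(horizon)

    @property
    def lifetime(self) -> HorizonSummary:
        return self.at("lifetime")


def run_cohort(config: ModelConfig, strategy: str | Strategy) -> CohortTrace:
    """Propagate the cohort for one strategy until extinction or max age.

    Stops when the alive fraction drops below ``engine.stop_epsilon``, the
    cohort reaches the maximum age, or ``engine.max_cycles`` cycles have
    run; in the latter cases a warning is recorded on the trace.
    """
    name = strategy.name if isinstance(strategy, Strategy) else strategy
    model = CompartmentModel(config, name)
    eng = config.engine
    horizon_cap = int(np.ceil(config.cohort.max_age - config.cohort.mean_age))
    max_cycles = min(eng.max_cycles, horizon_cap)
    occ = model.start_vector()
    rows = [occ]
    stay = []
    converged = False
    for t in range(1, max_cycles + 1):
        age = config.cohort.mean_age + t - 1
        M = model.matrix(age)
        stay.append(np.diag(M).copy())
        occ = occ @ M
        rows.append(occ)
        if 1.0 - occ[model.dead_index] < eng.stop_epsilon:
            converged = True
            break
    comp = np.vstack(rows)
    warning = None
    if not converged:
        alive = 1.0 - comp[-1, model.dead_index]
        warning = (
            f"cohort not extinct after {len(rows) - 1} cycles "
            f"(alive fraction {alive:.3g})"
        )
    return CohortTrace(
        strategy=name,
        occupancy=model.aggregate(comp),
        compartments=comp,
        compartment_labels=model.labels,
        stay_probs=np.vstack(stay),
        cycles_run=len(rows) - 1,
        converged=converged,
        warning=warning,
    )


def discount_factor(
    cycle_index: int, rate: float, convention: str = "first_cycle_undiscounted"
) -> float:
    """Discount factor (1 + rate)^-cycle_index; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if convention != "first_cycle_undiscounted":
        raise ValueError(f"unknown discounting convention: {convention!r}")
    return float((1.0 + rate) ** (-cycle_index))


def expected_cycle_cost(
    trace_row: np.ndarray,
    costs: np.ndarray,
    matrix: TransitionMatrix | np.ndarray | None,
    weighting: str = "stay_probability",
) -> float:
    """Expected cohort cost of one cycle under the chosen weighting.

    ``stay_probability`` multiplies each state's cost by the probability of
    remaining in that state for the cycle, i.e. sum_s occ_s c_s (1 - exit_s)
    — the source model's stated rule. ``occupancy`` is the conventional
    sum_s occ_s c_s.
    """
    row = np.asarray(trace_row, dtype=float)
    c = np.asarray(costs, dtype=float)
    if weighting == "occupancy":
        return float(row @ c)
    if weighting != "stay_probability":
        raise ValueError(f"unknown cost weighting: {weighting!r}")
    if matrix is None:
        raise ValueError("stay_probability weighting needs the cycle matrix")
    arr = matrix.array if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    stay = np.diag(arr) if arr.ndim == 2 else arr
    return float(row @ (c * stay))


def accumulate(trace: CohortTrace, config: ModelConfig) -> AccumulationResult:
    """Per-cycle outcomes and cumulative summaries at the fixed horizons.

    Rewards accrue on end-of-cycle occupancy (or on the start/end average
    when the half-cycle correction is switched on). Horizons that exceed the
    realized trace fall back to lifetime values and are flagged.
    """
    model = CompartmentModel(config, trace.strategy)
    cost_vec = model.cost_vector()
    util_vec = model.utility_vector()
    eng = config.engine
    disc = config.discount
    T = trace.cycles_run

    cost_u = np.zeros(T)
    cost_d = np.zeros(T)
    ly = np.zeros(T)
    qaly = np.zeros(T)
    breakdown = np.zeros((T, N_STATES))
    for t in range(1, T + 1):
        row = trace.compartments[t]
        if eng.half_cycle_correction:
            row = 0.5 * (trace.compartments[t - 1] + row)
        stay = trace.stay_probs[t - 1]
        dc = discount_factor(t - 1, disc.rate_costs, disc.convention)
        do = discount_factor(t - 1, disc.rate_outcomes, disc.convention)
        if eng.cost_weighting == "stay_probability":
            per_comp = row * cost_vec * stay
        else:
            per_comp = row * cost_vec
        cost_u[t - 1] = per_comp.sum()
        cost_d[t - 1] = cost_u[t - 1] * dc
        alive = 1.0 - row[model.dead_index]
        ly[t - 1] = alive * do
        # state-specific utilities; the cohort-average mode (alive fraction
        # times mean utility of the living) is algebraically identical
        qaly[t - 1] = float(row @ util_vec) * do
        breakdown[t - 1] = model.aggregate(per_comp[None, :])[0] * dc

    cycles = pd.DataFrame(
        {
            "cycle": np.arange(1, T + 1),
            "undiscounted_cost": cost_u,
            "discounted_cost": cost_d,
            "life_years": ly,
            "qalys": qaly,
        }
    )
    for i, s in enumerate(STATES):
        cycles[f"cost_{s.value}"] = breakdown[:, i]

    cum_cd = np.cumsum(cost_d)
    cum_cu = np.cumsum(cost_u)
    cum_ly = np.cumsum(ly)
    cum_q = np.cumsum(qaly)
    horizons: list[HorizonSummary] = []
    for y in HORIZON_YEARS:
        idx = min(y, T) - 1
        horizons.append(
            HorizonSummary(
                horizon=f"{y}y",
                years=y,
                cost=float(cum_cd[idx]),
                undiscounted_cost=float(cum_cu[idx]),
                life_years=float(cum_ly[idx]),
                qalys=float(cum_q[idx]),
                truncated=y > T,
            )
        )
    horizons.append(
        HorizonSummary(
            horizon="lifetime",
            years=T,
            cost=float(cum_cd[-1]),
            undiscounted_cost=float(cum_cu[-1]),
            life_years=float(cum_ly[-1]),
            qalys=float(cum_q[-1]),
        )
    )
    return AccumulationResult(
        strategy=trace.strategy,
        horizons=horizons,
        cycles=cycles,
        cost_weighting=eng.cost_weighting,
        qaly_mode=eng.qaly_mode,
    )


def trace_frame(trace: CohortTrace, accum: AccumulationResult | None = None) -> pd.DataFrame:
    """Trace as a tidy table, one row per cycle, deterministic column order."""
    T = trace.cycles_run
    df = pd.DataFrame({"cycle": np.arange(T + 1)})
    for i, s in enumerate(STATES):
        df[s.value] = trace.occupancy[:, i]
    if trace.compartments.shape[1] != N_STATES:
        for j, lab in enumerate(trace.compartment_labels):
            if lab not in df.columns:
                df[lab] = trace.compartments[:, j]
    if accum is not None:
        for col in ("undiscounted_cost", "discounted_cost", "life_years", "qalys"):
            df[col] = np.concatenate([[0.0], accum.cycles[col].to_numpy()])
    return df
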