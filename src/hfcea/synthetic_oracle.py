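"""Individual-level Monte-Carlo oracle and random-scenario generator.

``simulate_individuals`` runs the exact same annual-cycle transition process
as the cohort engine, one simulated patient at a time (vectorized), with the
same reward conventions (end-of-cycle accrual, stay-probability cost
weighting, discounting). Its empirical state occupancy converges to the
cohort trace at rate sqrt(p(1-p)/n), which makes it an independent
validation oracle for the deterministic engine.

``generate_scenario`` draws random but always-valid model configurations
(row-stochastic progressive matrices, positive costs, utilities in [0, 1])
for property testing of the engine on inputs far from the shipped base case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .markov_engine import CompartmentModel, discount_factor
from .parameters import ModelConfig, N_STATES

__all__ = ["MicrosimResult", "ScenarioSpec", "simulate_individuals", "generate_scenario"]


@dataclass
class MicrosimResult:
    """Empirical occupancy and per-individual reward means from microsimulation."""

    strategy: str
    n: int
    seed: int
    occupancy: np.ndarray        # (cycles+1, 5) empirical state fractions
    standard_errors: np.ndarray  # binomial SE per cell
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_life_years: float
    se_life_years: float
    cycles_run: int


def simulate_individuals(
    config: ModelConfig, strategy: str, n: int, seed: int
) -> MicrosimResult:
    """Simulate ``n`` independent patients through the strategy's chain.

    Each patient starts from the cohort start distribution and draws a
    categorical transition from their current compartment's matrix row every
    cycle until death or the engine's cycle cap. Reproducible for a fixed
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = CompartmentModel(config, strategy)
    eng = config.engine
    disc = config.discount
    horizon_cap = int(np.ceil(config.cohort.max_age - config.cohort.mean_age))
    max_cycles = min(eng.max_cycles, horizon_cap)

    rng = np.random.default_rng(seed)
    k = model.n
    start = model.start_vector()
    state = rng.choice(k, size=n, p=start)

    cost_vec = model.cost_vector()
    util_vec = model.utility_vector()
    alive_vec = np.ones(k)
    alive_vec[model.dead_index] = 0.0

    occ_rows = [np.bincount(state, minlength=k).astype(float) / n]
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    cycles = 0
    for t in range(1, max_cycles + 1):
        age = config.cohort.mean_age + t - 1
        M = model.matrix(age)
        stay = np.diag(M)
        cum = np.cumsum(M, axis=1)
        prev = state
        u = rng.random(n)
        state = np.empty(n, dtype=int)
        for j in range(k):
            mask = prev == j
            if mask.any():
                state[mask] = np.searchsorted(cum[j], u[mask], side="right")
        np.clip(state, 0, k - 1, out=state)
        cycles = t

        if eng.cost_weighting == "stay_probability":
            comp_cost = cost_vec * stay
        else:
            comp_cost = cost_vec
        dc = discount_factor(t - 1, disc.rate_costs, disc.convention)
        do = discount_factor(t - 1, disc.rate_outcomes, disc.convention)
        if eng.half_cycle_correction:
            cost += 0.5 * (comp_cost[prev] + comp_cost[state]) * dc
            qaly += 0.5 * (util_vec[prev] + util_vec[state]) * do
            ly += 0.5 * (alive_vec[prev] + alive_vec[state]) * do
        else:
            cost += comp_cost[state] * dc
            qaly += util_vec[state] * do
            ly += alive_vec[state] * do
        occ_rows.append(np.bincount(state, minlength=k).astype(float) / n)
        if (state == model.dead_index).all():
            break

    comp_occ = np.vstack(occ_rows)
    occupancy = model.aggregate(comp_occ)
    se = np.sqrt(occupancy * (1.0 - occupancy) / n)

    def mse(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return MicrosimResult(
        strategy=strategy,
        n=n,
        seed=seed,
        occupancy=occupancy,
        standard_errors=se,
        mean_cost=float(cost.mean()),
        se_cost=mse(cost),
        mean_qaly=float(qaly.mean()),
        se_qaly=mse(qaly),
        mean_life_years=float(ly.mean()),
        se_life_years=mse(ly),
        cycles_run=cycles,
    )


class ScenarioSpec(BaseModel):
    """Controls for the random-scenario generator (deterministic per seed)."""

    seed: int
    n_states: int = Field(default=N_STATES, frozen=True)
    max_progression: float = Field(gt=0.0, le=0.9, default=0.3)
    max_mortality: float = Field(gt=0.0, le=0.9, default=0.4)
    cost_scale: float = Field(gt=0.0, default=10_000.0)
    max_discount_rate: float = Field(ge=0.0, le=0.2, default=0.05)
    allow_detection: bool = True
    max_cycles: int = Field(ge=1, default=100)


def _random_transitions(rng: np.random.Generator, spec: ScenarioSpec) -> dict:
    mort = float(rng.uniform(0.01, spec.max_mortality))
    head = 1.0 - mort - 1e-6
    prog = rng.uniform(0.0, np.minimum(spec.max_progression, head), size=3)
    return {
        "stage_b_to_c": float(prog[0]),
        "stage_c_to_cplus": float(prog[1]),
        "stage_cplus_to_d": float(prog[2]),
        "hf_mortality": mort,
    }


def generate_scenario(spec: ScenarioSpec) -> ModelConfig:
    """A fully valid random model configuration.

    Matrices are progressive and row-stochastic by construction, costs are
    non-negative, utilities lie in [0, 1] and decrease with severity, and
    the Dead state is absorbing. Background mortality is switched off so the
    chain is time-homogeneous, which keeps scenarios analyzable by
    closed-form checks. Identical seeds give identical configurations.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.cost_scale

    def strategy(name: str, acc_lo: float, acc_hi: float) -> dict:
        return {
            "name": name,
            "diagnostic_accuracy": float(rng.uniform(acc_lo, acc_hi)),
            "test_cost": float(rng.uniform(0.0, 0.1) * scale),
            "test_reimbursement": float(rng.uniform(0.0, 0.1) * scale),
            "contrast_cost": float(rng.uniform(0.0, 0.02) * scale),
            "hospitalization_reduction": float(rng.uniform(0.0, 0.5)),
        }

    utils = np.sort(rng.uniform(0.05, 1.0, size=4))[::-1]
    split = rng.dirichlet(np.ones(3))
    raw = {
        "comparator": "ECHO",
        "intervention": "FastSENC",
        "strategies": {
            "ECHO": strategy("ECHO", 0.0, 0.5),
            "FastSENC": strategy("FastSENC", 0.5, 1.0),
        },
        "transitions": {
            "ECHO": _random_transitions(rng, spec),
            "FastSENC": _random_transitions(rng, spec),
        },
        "costs": {
            "office_visit_cost": float(rng.uniform(0.005, 0.05) * scale),
            "drug_cost_monthly": float(rng.uniform(0.005, 0.1) * scale),
            "advanced_drug_cost_monthly": float(rng.uniform(0.005, 0.15) * scale),
            "hf_hospitalization_prob": float(rng.uniform(0.05, 0.6)),
            "hf_hospitalization_cost": float(rng.uniform(0.5, 3.0) * scale),
            "rehospitalization_prob_30d": float(rng.uniform(0.0, 0.5)),
            "intervention_prob": float(rng.uniform(0.0, 0.5)),
            "intervention_cost": float(rng.uniform(0.5, 2.0) * scale),
            "palliative_cost": float(rng.uniform(0.1, 1.0) * scale),
            "assist_device_prob": float(rng.uniform(0.0, 0.5)),
            "assist_device_cost": float(rng.uniform(0.5, 3.0) * scale),
        },
        "utilities": {
            "StageB": float(utils[0]),
            "StageC": float(utils[1]),
            "StageCplus": float(utils[2]),
            "StageD": float(utils[3]),
            "Dead": 0.0,
        },
        "discount": {
            "rate_costs": float(rng.uniform(0.0, spec.max_discount_rate)),
            "rate_outcomes": float(rng.uniform(0.0, spec.max_discount_rate)),
            "convention": "first_cycle_undiscounted",
        },
        "cohort": {
            "mean_age": 64.0,
            "max_age": 110.0,
            "hf_pretest_prevalence": float(rng.uniform(0.05, 0.5)),
            "hf_stage_split": [float(x) for x in split],
            "stageB_4yr_progression": float(rng.uniform(0.0, 0.5)),
            "background_mortality": {"ages": [0.0, 120.0], "probs": [0.0, 0.0]},
        },
        "detection": {
            "enabled": bool(rng.integers(0, 2)) if spec.allow_detection else False,
            "post_hosp_diagnosis_rate": float(rng.uniform(0.0, 1.0)),
            "annual_rescreening": bool(rng.integers(0, 2)),
        },
        "engine": {
            "stop_epsilon": 1e-9,
            "max_cycles": spec.max_cycles,
            "cost_weighting": ["stay_probability", "occupancy"][int(rng.integers(0, 2))],
            "qaly_mode": "state_specific",
            "half_cycle_correction": False,
            "apply_background_mortality": False,
            "stage_b_hf_mortality": bool(rng.integers(0, 2)),
        },
    }
    return ModelConfig.model_validate(raw)
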