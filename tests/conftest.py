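import pytest

from hfcea.parameters import ModelConfig, default_config

DEFAULT_BG = {"ages": [0.0, 120.0], "probs": [0.0, 0.0]}


def make_toy_config(
    *,
    mortality: float = 0.1,
    progression: tuple[float, float, float] = (0.0, 0.0, 0.0),
    utilities: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    office: float = 0.0,
    drug: float = 0.0,
    adrug: float = 0.0,
    test_cost: float = 0.0,
    rate: float = 0.0,
    prevalence: float = 0.0,
    detection: bool = False,
    cost_weighting: str = "stay_probability",
    half_cycle: bool = False,
    max_cycles: int = 500,
    mean_age: float = 64.0,
    max_age: float | None = None,
    hf_hosp_prob: float = 0.0,
    intervention_prob: float = 0.0,
) -> ModelConfig:
    """A minimal 5-state configuration for closed-form checks.

    With zero progression and prevalence the whole cohort sits in Stage B
    and the chain reduces to a single living state with constant death
    probability ``mortality``.
    """
    if max_age is None:
        max_age = mean_age + max_cycles  # let max_cycles be the binding cap
    p1, p2, p3 = progression
    strat = {
        "diagnostic_accuracy": 1.0,
        "test_cost": test_cost,
        "test_reimbursement": test_cost,
        "contrast_cost": 0.0,
        "hospitalization_reduction": 0.0,
    }
    trans = {
        "stage_b_to_c": p1,
        "stage_c_to_cplus": p2,
        "stage_cplus_to_d": p3,
        "hf_mortality": mortality,
    }
    raw = {
        "comparator": "ECHO",
        "intervention": "FastSENC",
        "strategies": {
            "ECHO": {"name": "ECHO", **strat},
            "FastSENC": {"name": "FastSENC", **strat},
        },
        "transitions": {"ECHO": dict(trans), "FastSENC": dict(trans)},
        "costs": {
            "office_visit_cost": office,
            "drug_cost_monthly": drug,
            "advanced_drug_cost_monthly": adrug,
            "hf_hospitalization_prob": hf_hosp_prob,
            "hf_hospitalization_cost": 0.0,
            "rehospitalization_prob_30d": 0.0,
            "intervention_prob": intervention_prob,
            "intervention_cost": 0.0,
            "palliative_cost": 0.0,
            "assist_device_prob": 0.0,
            "assist_device_cost": 0.0,
        },
        "utilities": {
            "StageB": utilities[0],
            "StageC": utilities[1],
            "StageCplus": utilities[2],
            "StageD": utilities[3],
            "Dead": 0.0,
        },
        "discount": {"rate_costs": rate, "rate_outcomes": rate},
        "cohort": {
            "mean_age": mean_age,
            "max_age": max_age,
            "hf_pretest_prevalence": prevalence,
            "hf_stage_split": [1.0, 0.0, 0.0],
            "stageB_4yr_progression": 0.0,
            "background_mortality": DEFAULT_BG,
        },
        "detection": {"enabled": detection, "post_hosp_diagnosis_rate": 0.5},
        "engine": {
            "stop_epsilon": 1e-9,
            "max_cycles": max_cycles,
            "cost_weighting": cost_weighting,
            "half_cycle_correction": half_cycle,
            "apply_background_mortality": False,
            "stage_b_hf_mortality": True,
        },
    }
    return ModelConfig.model_validate(raw)


@pytest.fixture(scope="session")
def default_cfg() -> ModelConfig:
    return default_config()
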