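"""Cohort propagation, costing, discounting and horizon accumulation."""

import numpy as np
import pytest

from hfcea.markov_engine import (
    accumulate,
    discount_factor,
    expected_cycle_cost,
    run_cohort,
    state_cycle_cost,
    trace_frame,
)
from hfcea.parameters import DiseaseState, default_config
from hfcea.synthetic_oracle import ScenarioSpec, generate_scenario

from conftest import make_toy_config


class TestRunCohort:
    def test_identity_chain_keeps_occupancy_constant(self):
        cfg = make_toy_config(mortality=0.0, max_cycles=25)
        trace = run_cohort(cfg, "ECHO")
        assert trace.cycles_run == 25
        assert not trace.converged
        assert trace.warning is not None
        np.testing.assert_allclose(
            trace.occupancy - trace.occupancy[0], 0.0, atol=1e-14
        )

    def test_geometric_survival_of_single_state_chain(self):
        # stay 0.9 / die 0.1: alive fraction after cycle t is 0.9^t
        cfg = make_toy_config(mortality=0.1)
        trace = run_cohort(cfg, "ECHO")
        assert trace.alive[3] == pytest.approx(0.729, abs=1e-12)
        assert trace.alive[10] == pytest.approx(0.9**10, abs=1e-12)
        assert trace.converged

    def test_start_row_matches_cohort_spec(self, default_cfg):
        for name in default_cfg.strategies:
            trace = run_cohort(default_cfg, name)
            np.testing.assert_allclose(
                trace.occupancy[0], default_cfg.cohort.start_distribution(), atol=1e-14
            )

    def test_dead_occupancy_monotone_nondecreasing(self, default_cfg):
        for name in default_cfg.strategies:
            trace = run_cohort(default_cfg, name)
            dead = trace.occupancy[:, -1]
            assert np.all(np.diff(dead) > 0)  # positive mortality every cycle

    @pytest.mark.parametrize("seed", range(8))
    def test_probability_conservation_on_random_scenarios(self, seed):
        cfg = generate_scenario(ScenarioSpec(seed=seed))
        for name in cfg.strategies:
            trace = run_cohort(cfg, name)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), 1.0, atol=1e-10
            )
            np.testing.assert_allclose(
                trace.compartments.sum(axis=1), 1.0, atol=1e-10
            )
            dead = trace.occupancy[:, -1]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_lifetime_life_years_match_geometric_series(self):
        # single living state, death probability p, no discounting:
        # expected residence time is 1/p (geometric series)
        p = 0.005
        cfg = make_toy_config(
            mortality=p, rate=0.0, max_age=6000.0, max_cycles=100_000
        )
        trace = run_cohort(cfg, "ECHO")
        assert trace.converged
        acc = accumulate(trace, cfg)
        assert acc.lifetime.life_years == pytest.approx(1 / p, rel=0.01)


class TestStateCycleCost:
    def test_dead_costs_nothing(self, default_cfg):
        strat = default_cfg.strategies["ECHO"]
        assert state_cycle_cost(DiseaseState.DEAD, default_cfg.costs, strat) == 0.0

    def test_stage_b_echo_component_sum(self, default_cfg):
        # visits 165 + drugs 12*367 + scan 231 + contrast 45
        strat = default_cfg.strategies["ECHO"]
        cost = state_cycle_cost(DiseaseState.STAGE_B, default_cfg.costs, strat)
        assert cost == pytest.approx(4845.0, abs=1e-9)

    def test_stage_cplus_hospitalization_expectation(self):
        # hosp 0.3202 * $23,077 * (1 + 0.269) with no advanced drugs
        cfg = make_toy_config(hf_hosp_prob=0.3202)
        data = cfg.model_dump()
        data["costs"]["hf_hospitalization_cost"] = 23077.0
        data["costs"]["rehospitalization_prob_30d"] = 0.269
        from hfcea.parameters import ModelConfig

        cfg = ModelConfig.model_validate(data)
        cost = state_cycle_cost(
            DiseaseState.STAGE_C_PLUS, cfg.costs, cfg.strategies["ECHO"]
        )
        assert cost == pytest.approx(0.3202 * 23077 * 1.269, abs=1e-9)

    def test_reduction_lowers_stage_cplus_cost(self, default_cfg):
        c = default_cfg.costs
        echo = state_cycle_cost(
            DiseaseState.STAGE_C_PLUS, c, default_cfg.strategies["ECHO"]
        )
        fs = state_cycle_cost(
            DiseaseState.STAGE_C_PLUS, c, default_cfg.strategies["FastSENC"]
        )
        assert fs < echo


class TestExpectedCycleCost:
    def test_stay_probability_discounts_exits(self):
        row = np.array([1.0])
        costs = np.array([100.0])
        stay = np.array([0.7])  # exit probability 0.3
        assert expected_cycle_cost(row, costs, stay) == pytest.approx(70.0)
        assert expected_cycle_cost(row, costs, None, "occupancy") == pytest.approx(100.0)

    def test_modes_agree_without_exits(self):
        row = np.array([0.3, 0.7])
        costs = np.array([10.0, 20.0])
        stay = np.ones(2)
        assert expected_cycle_cost(row, costs, stay) == pytest.approx(
            expected_cycle_cost(row, costs, None, "occupancy")
        )


class TestDiscountFactor:
    def test_published_rate_examples(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(1, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=1e-6)

    def test_zero_rate_never_discounts(self):
        for t in (0, 1, 17):
            assert discount_factor(t, 0.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestAccumulate:
    def test_unit_utilities_make_qalys_equal_life_years(self):
        cfg = make_toy_config(
            mortality=0.08, progression=(0.05, 0.05, 0.05), utilities=(1, 1, 1, 1)
        )
        acc = accumulate(run_cohort(cfg, "ECHO"), cfg)
        for h in acc.horizons:
            assert h.qalys == pytest.approx(h.life_years, abs=1e-12)

    def test_three_immortal_cycles_at_point_eight_utility(self):
        # alive forever at utility 0.8, no discounting: 3-year QALY = 2.4
        cfg = make_toy_config(mortality=0.0, utilities=(0.8, 0.8, 0.8, 0.8), max_cycles=10)
        acc = accumulate(run_cohort(cfg, "ECHO"), cfg)
        assert acc.at("3y").qalys == pytest.approx(2.4, abs=1e-12)

    def test_discounted_cost_bounded_by_undiscounted(self, default_cfg):
        acc = accumulate(run_cohort(default_cfg, "ECHO"), default_cfg)
        for h in acc.horizons:
            assert h.cost <= h.undiscounted_cost + 1e-9

    def test_zero_rate_removes_discounting(self):
        cfg = make_toy_config(mortality=0.1, office=1000.0, rate=0.0)
        acc = accumulate(run_cohort(cfg, "ECHO"), cfg)
        for h in acc.horizons:
            assert h.cost == pytest.approx(h.undiscounted_cost, abs=1e-9)

    def test_horizon_summaries_nondecreasing(self, default_cfg):
        for name in default_cfg.strategies:
            acc = accumulate(run_cohort(default_cfg, name), default_cfg)
            costs = [h.cost for h in acc.horizons]
            lys = [h.life_years for h in acc.horizons]
            qalys = [h.qalys for h in acc.horizons]
            for seq in (costs, lys, qalys):
                assert all(a <= b + 1e-9 for a, b in zip(seq, seq[1:]))

    def test_truncated_horizons_fall_back_to_lifetime(self):
        cfg = make_toy_config(mortality=0.9)  # near-immediate extinction
        trace = run_cohort(cfg, "ECHO")
        acc = accumulate(trace, cfg)
        ten = acc.at("10y")
        if trace.cycles_run < 10:
            assert ten.truncated
            assert ten.cost == pytest.approx(acc.lifetime.cost)

    def test_stay_probability_mode_cheaper_than_occupancy(self):
        kwargs = dict(mortality=0.1, office=1000.0)
        stay = make_toy_config(cost_weighting="stay_probability", **kwargs)
        occ = make_toy_config(cost_weighting="occupancy", **kwargs)
        c_stay = accumulate(run_cohort(stay, "ECHO"), stay).lifetime.cost
        c_occ = accumulate(run_cohort(occ, "ECHO"), occ).lifetime.cost
        assert c_stay < c_occ
        assert c_stay == pytest.approx(0.9 * c_occ, rel=1e-9)  # uniform stay prob

    def test_half_cycle_correction_averages_boundary(self):
        plain = make_toy_config(mortality=0.2, office=100.0, rate=0.0)
        half = make_toy_config(mortality=0.2, office=100.0, rate=0.0, half_cycle=True)
        ly_plain = accumulate(run_cohort(plain, "ECHO"), plain).lifetime.life_years
        ly_half = accumulate(run_cohort(half, "ECHO"), half).lifetime.life_years
        # trapezoid adds half of the first (full) cycle relative to end-of-cycle accrual
        assert ly_half == pytest.approx(ly_plain + 0.5, abs=1e-6)


class TestTraceExport:
    def test_frame_has_deterministic_layout(self, default_cfg):
        trace = run_cohort(default_cfg, "FastSENC")
        acc = accumulate(trace, default_cfg)
        df = trace_frame(trace, acc)
        assert list(df.columns[:6]) == [
            "cycle",
            "StageB",
            "StageC",
            "StageCplus",
            "StageD",
            "Dead",
        ]
        assert len(df) == trace.cycles_run + 1
        np.testing.assert_allclose(
            df[["StageB", "StageC", "StageCplus", "StageD", "Dead"]].sum(axis=1),
            1.0,
            atol=1e-10,
        )
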