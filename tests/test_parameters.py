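"""Input validation, matrix construction and rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcea.parameters import (
    LIVING_STATES,
    ConfigError,
    DiseaseState,
    InfeasibleRowError,
    MatrixError,
    ModelConfig,
    TransitionMatrix,
    annualize_probability,
    apply_hospitalization_reduction,
    build_transition_matrix,
    default_config,
    load_config,
    save_config,
)

B, C, CP, D = LIVING_STATES


class TestConfigLoading:
    def test_default_config_carries_published_inputs(self, default_cfg):
        assert default_cfg.transitions["ECHO"].stage_b_to_c == 0.0427
        assert default_cfg.transitions["ECHO"].hf_mortality == 0.0694
        assert default_cfg.transitions["FastSENC"].stage_b_to_c == 0.0311
        assert default_cfg.costs.hf_hospitalization_cost == 23077.0
        assert default_cfg.costs.hf_hospitalization_prob == 0.3202
        assert default_cfg.strategies["FastSENC"].hospitalization_reduction == 0.271
        assert default_cfg.utilities.StageCplus == 0.65
        assert default_cfg.discount.rate_costs == 0.03
        assert default_cfg.cohort.mean_age == 64.0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ConfigError, match="not found"):
            load_config(tmp_path / "nope.yaml")

    def test_schema_violation_names_field(self, tmp_path):
        cfg = default_config()
        data = cfg.model_dump(mode="json")
        data["costs"]["drug_cost_monthly"] = -5
        import yaml

        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(data))
        with pytest.raises(ConfigError, match="drug_cost_monthly"):
            load_config(p)

    def test_infeasible_transition_row_rejected(self, tmp_path):
        cfg = default_config()
        data = cfg.model_dump(mode="json")
        data["transitions"]["ECHO"]["stage_b_to_c"] = 0.98
        import yaml

        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(data))
        with pytest.raises((ConfigError, InfeasibleRowError)):
            load_config(p)

    def test_round_trip_preserves_config(self, default_cfg, tmp_path):
        p = tmp_path / "rt.yaml"
        save_config(default_cfg, p)
        again = load_config(p)
        assert again.model_dump() == default_cfg.model_dump()

    def test_start_distribution_derived_from_prevalence_and_split(self, default_cfg):
        start = default_cfg.cohort.start_distribution()
        np.testing.assert_allclose(start, [0.9, 0.05, 0.05, 0.0, 0.0])
        assert start.sum() == pytest.approx(1.0)


class TestTransitionMatrix:
    def test_row_sum_failure_names_row(self):
        rows = np.eye(5)
        rows[1, 1] = 0.95  # row sums to 0.95
        with pytest.raises(MatrixError, match="StageC"):
            TransitionMatrix(entries=rows.tolist())

    def test_backward_transition_rejected(self):
        rows = np.eye(5)
        rows[2, 2] = 0.9
        rows[2, 0] = 0.1  # C+ -> B is a recovery, not allowed
        with pytest.raises(MatrixError, match="backward"):
            TransitionMatrix(entries=rows.tolist())

    def test_dead_must_be_absorbing(self):
        rows = np.eye(5)
        rows[4, 4] = 0.9
        rows[4, 3] = 0.1
        with pytest.raises(MatrixError):
            TransitionMatrix(entries=rows.tolist())


class TestBuildTransitionMatrix:
    def test_stage_b_self_stay_from_published_inputs(self):
        m = build_transition_matrix({B: 0.0427}, 0.0694, 0.0)
        assert m.array[0, 0] == pytest.approx(1 - 0.0427 - 0.0694, abs=1e-12)
        assert m.array[0, 0] == pytest.approx(0.8879, abs=1e-12)

    def test_all_zero_inputs_give_identity_on_living(self):
        m = build_transition_matrix({}, 0.0, 0.0)
        np.testing.assert_allclose(m.array, np.eye(5))

    def test_fastsenc_inputs_produce_valid_matrix(self):
        m = build_transition_matrix(
            {B: 0.0311, C: 0.0332, CP: 0.0328}, 0.0543, 0.0
        )
        np.testing.assert_allclose(m.array.sum(axis=1), 1.0, atol=1e-12)
        assert m.array[4, 4] == 1.0

    def test_background_mortality_combines_independently(self):
        m = build_transition_matrix({}, 0.0694, 0.0131)
        expected = 1 - (1 - 0.0694) * (1 - 0.0131)
        assert m.array[0, 4] == pytest.approx(expected, abs=1e-12)

    def test_stage_b_background_only_switch(self):
        m = build_transition_matrix({}, 0.0694, 0.0131, stage_b_hf_mortality=False)
        assert m.array[0, 4] == pytest.approx(0.0131, abs=1e-12)
        assert m.array[1, 4] == pytest.approx(1 - (1 - 0.0694) * (1 - 0.0131))

    def test_overallocated_row_is_infeasible(self):
        with pytest.raises(InfeasibleRowError):
            build_transition_matrix({B: 0.6}, 0.5, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.floats(0, 0.4),
        dp=st.floats(0, 0.1),
        mort=st.floats(0, 0.4),
        dm=st.floats(0, 0.1),
    )
    def test_self_stay_monotone_in_progression_and_mortality(self, p, dp, mort, dm):
        base = build_transition_matrix({B: p}, mort, 0.0).array[0, 0]
        more_prog = build_transition_matrix({B: p + dp}, mort, 0.0).array[0, 0]
        more_mort = build_transition_matrix({B: p}, mort + dm, 0.0).array[0, 0]
        assert more_prog <= base + 1e-12
        assert more_mort <= base + 1e-12


class TestHospitalizationReduction:
    def test_half_of_preventable_gives_published_reduction(self):
        r = apply_hospitalization_reduction(0.3202, 0.542, 0.5)
        assert r.relative_reduction == pytest.approx(0.271, abs=1e-12)

    def test_reduced_rate_closed_form(self):
        r = apply_hospitalization_reduction(0.3202, 0.542, 0.5)
        assert r.rate == pytest.approx(0.3202 * (1 - 0.271), abs=1e-12)

    def test_zero_capture_leaves_rate_unchanged(self):
        assert apply_hospitalization_reduction(0.3202, 0.542, 0.0).rate == 0.3202

    @settings(max_examples=100, deadline=None)
    @given(
        base=st.floats(0, 1),
        prev=st.floats(0, 1),
        cap=st.floats(0, 1),
    )
    def test_reduction_never_exceeds_base(self, base, prev, cap):
        r = apply_hospitalization_reduction(base, prev, cap)
        assert r.rate <= base + 1e-15
        if prev * cap == 0:
            assert r.rate == pytest.approx(base)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_hospitalization_reduction(1.2, 0.5, 0.5)


class TestAnnualizeProbability:
    def test_four_year_stage_b_progression(self):
        # 1 - (1 - 0.154)^(1/4)
        assert annualize_probability(0.154, 4) == pytest.approx(0.0409470, abs=1e-6)

    def test_zero_stays_zero(self):
        assert annualize_probability(0.0, 7) == 0.0

    def test_one_year_is_identity(self):
        assert annualize_probability(0.37, 1) == pytest.approx(0.37)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            annualize_probability(1.0, 4)

    @settings(max_examples=100, deadline=None)
    @given(p=st.floats(0, 0.999), years=st.integers(1, 30))
    def test_compounding_recovers_multi_year_probability(self, p, years):
        annual = annualize_probability(p, years)
        assert 1 - (1 - annual) ** years == pytest.approx(p, abs=1e-12)


class TestModelConfigInvariants:
    def test_two_strategies_required(self, default_cfg):
        data = default_cfg.model_dump()
        del data["strategies"]["ECHO"]
        with pytest.raises(Exception, match="two strategies|missing"):
            ModelConfig.model_validate(data)

    def test_strategy_name_key_agreement(self, default_cfg):
        data = default_cfg.model_dump()
        data["strategies"]["ECHO"]["name"] = "Echo"
        with pytest.raises(Exception, match="disagrees"):
            ModelConfig.model_validate(data)

    def test_stage_split_must_sum_to_one(self, default_cfg):
        data = default_cfg.model_dump()
        data["cohort"]["hf_stage_split"] = [0.5, 0.5, 0.5]
        with pytest.raises(Exception, match="sum to 1"):
            ModelConfig.model_validate(data)

    def test_dead_utility_pinned_at_zero(self, default_cfg):
        data = default_cfg.model_dump()
        data["utilities"]["Dead"] = 0.1
        with pytest.raises(Exception, match="Dead"):
            ModelConfig.model_validate(data)

    def test_background_mortality_interpolates(self, default_cfg):
        bm = default_cfg.cohort.background_mortality
        q64 = bm.at(64.0)
        assert bm.at(60.0) == pytest.approx(0.00949)
        assert 0.00949 < q64 < 0.01503
        assert bm.at(130.0) == pytest.approx(bm.at(110.0))
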