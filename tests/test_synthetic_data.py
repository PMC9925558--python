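"""Race-model simulator: staircase, outcome rules, distributional identities."""

import numpy as np
import pandas as pd
import pytest

from selstop.synthetic_data import (
    CohortConfig,
    StaircaseState,
    SubjectParams,
    classify_go_response,
    simulate_cohort,
    simulate_mep,
    simulate_session,
    simulate_trial,
    solve_shifted_lognormal,
)
from selstop.task_design import TrialSpec


def _stop_spec(trial_type="left_stop", condition="reactive"):
    cue = "fixation" if condition == "reactive" else (
        "MSL" if trial_type == "left_stop" else "MSR")
    return TrialSpec("P", "main", condition, cue, trial_type, 0, 0)


class TestStaircase:
    @pytest.mark.parametrize("ssd,responded,expected", [
        (200.0, False, 250.0),   # successful stop -> SSD harder
        (200.0, True, 150.0),
        (100.0, True, 50.0),
        (50.0, True, 50.0),      # floor
        (50.0, False, 100.0),
    ])
    def test_updates(self, ssd, responded, expected):
        spec = _stop_spec()
        state = StaircaseState(init=ssd)
        state.ssd(spec)
        state.update(spec, responded=responded)
        assert state.ssd(spec) == expected

    def test_keys_independent_per_hand_and_scope(self):
        state = StaircaseState()
        left, right = _stop_spec("left_stop"), _stop_spec("right_stop")
        pro_left = _stop_spec("left_stop", "proactive")
        state.update(left, responded=True)
        assert state.ssd(left) == 150.0
        assert state.ssd(right) == 200.0
        assert state.ssd(pro_left) == 200.0

    def test_go_trial_has_no_staircase_key(self):
        spec = TrialSpec("P", "main", "reactive", "fixation", "go", 0, 0)
        with pytest.raises(ValueError):
            StaircaseState.key_for(spec)


class TestGoClassification:
    @pytest.mark.parametrize("d,outcome", [
        (49.0, "go_correct"), (50.0, "go_async_error"), (51.0, "go_async_error")])
    def test_synchrony_threshold(self, d, outcome):
        assert classify_go_response(400.0, 400.0 + d)[0] == outcome

    def test_async_feedback_label(self):
        assert classify_go_response(400.0, 460.0) == (
            "go_async_error", "Press simultaneously")

    def test_missing_presses(self):
        assert classify_go_response(None, None)[0] == "go_missed"
        assert classify_go_response(400.0, None)[0] == "go_incomplete"

    def test_too_slow_flag_relative_to_go_only_mean(self):
        assert classify_go_response(700.0, 700.0, go_ref_rt=400.0)[0] == \
            "go_too_slow_flag"
        assert classify_go_response(640.0, 640.0, go_ref_rt=400.0)[0] == \
            "go_correct"


class TestStopTrials:
    def test_unwinnable_race_marches_to_floor(self, rng):
        params = SubjectParams(ssrt_true={"reactive": 1e9, "proactive": 1e9},
                               p_omission=0.0, p_wrong_hand=0.0)
        state = StaircaseState()
        spec = _stop_spec()
        outcomes = []
        for _ in range(40):
            res, state = simulate_trial(spec, params, state, rng)
            outcomes.append(res.outcome)
        assert set(outcomes) <= {"stop_fail", "stop_premature_response"}
        assert state.ssd(spec) == 50.0

    def test_certain_stop_success_has_single_rt(self, rng):
        params = SubjectParams(ssrt_true={"reactive": 1.0, "proactive": 1.0},
                               p_omission=0.0, p_wrong_hand=0.0)
        state = StaircaseState(init=50.0)
        res, _ = simulate_trial(_stop_spec("left_stop"), params, state, rng)
        assert res.outcome == "stop_success"
        assert res.rt_left is None and res.rt_right is not None

    def test_ssd_recorded_only_on_stop_trials(self, default_session):
        stop = default_session["trial_type"] != "go"
        assert default_session.loc[stop, "ssd"].notna().all()
        assert default_session.loc[~stop, "ssd"].isna().all()


class TestDistributionalIdentities:
    def test_lognormal_moment_solver(self):
        mu, sigma = solve_shifted_lognormal(430.0, 89.0, 150.0)
        m = 150.0 + np.exp(mu + sigma**2 / 2)
        sd = (m - 150.0) * np.sqrt(np.expm1(sigma**2))
        assert m == pytest.approx(430.0)
        assert sd == pytest.approx(89.0)

    def test_signal_respond_rt_below_go_rt(self, default_session):
        # race-model truncation: failed stops select fast finishing times
        main = default_session[default_session["phase"] == "main"]
        go = main[main["outcome"].isin(("go_correct", "go_too_slow_flag"))]
        go_rt = ((go["rt_left"] + go["rt_right"]) / 2).mean()
        fails = main[main["outcome"] == "stop_fail"]
        sr_rt = ((fails["rt_left"] + fails["rt_right"]) / 2).mean()
        assert sr_rt < go_rt

    def test_staircase_targets_half_stop_success(self, default_session):
        main = default_session[default_session["phase"] == "main"]
        stop = main[main["trial_type"] != "go"]
        p_succ = (stop["outcome"] == "stop_success").mean()
        assert 0.35 < p_succ < 0.65  # single subject; cohort-level is tighter

    def test_lapse_free_generator_has_no_go_errors(self):
        params = SubjectParams(sync_jitter_sd=0.0, p_omission=0.0,
                               p_wrong_hand=0.0)
        df = simulate_session("S", params, rng_seed=9)
        go = df[df["trial_type"] == "go"]
        assert not go["outcome"].isin(
            ("go_async_error", "go_incomplete", "go_missed")).any()


class TestMepGenerator:
    def test_requires_tms_trial(self, rng):
        spec = TrialSpec("P", "main", "reactive", "fixation", "go", 0, 0)
        with pytest.raises(ValueError):
            simulate_mep(spec, SubjectParams(), rng)

    def test_cse_emits_two_hands_conditioned_one(self, rng):
        base = dict(participant_id="P", phase="main", condition="reactive",
                    cue="fixation", trial_type="go", block_index=0,
                    trial_index_in_block=0, tms_timepoint="WS")
        cse = simulate_mep(TrialSpec(**base, tms_type="CSE"), SubjectParams(), rng)
        assert sorted(r["measured_hand"] for r in cse) == ["left", "right"]
        lihi = simulate_mep(TrialSpec(**base, tms_type="LIHI_LR"),
                            SubjectParams(), rng)
        assert [r["measured_hand"] for r in lihi] == ["left"]

    def test_conditioning_ratio_recovered(self, rng):
        params = SubjectParams()
        base = dict(participant_id="P", phase="main", condition="reactive",
                    cue="fixation", trial_type="go", block_index=0,
                    trial_index_in_block=0, tms_timepoint="WS")
        cse = [simulate_mep(TrialSpec(**base, tms_type="CSE"), params, rng)[0]
               ["amplitude"] for _ in range(4000)]
        sihi = [simulate_mep(TrialSpec(**base, tms_type="SIHI_LR"), params, rng)[0]
                ["amplitude"] for _ in range(4000)]
        ratio = np.mean(sihi) / np.mean(cse)
        assert ratio == pytest.approx(0.69, abs=0.04)

    def test_null_conditioning_matches_unconditioned_mean(self, rng):
        params = SubjectParams()
        params.ihi_ratio_true = {k: 1.0 for k in params.ihi_ratio_true}
        base = dict(participant_id="P", phase="main", condition="reactive",
                    cue="fixation", trial_type="go", block_index=0,
                    trial_index_in_block=0, tms_timepoint="WS")
        cond = [simulate_mep(TrialSpec(**base, tms_type="LIHI_LR"), params, rng)[0]
                ["amplitude"] for _ in range(4000)]
        assert np.mean(cond) == pytest.approx(params.mep_scale["WS_baseline"],
                                              rel=0.05)

    def test_forced_contamination_flags_every_record(self, rng):
        params = SubjectParams(p_emg_contaminated=1.0)
        base = dict(participant_id="P", phase="main", condition="reactive",
                    cue="fixation", trial_type="go", block_index=0,
                    trial_index_in_block=0, tms_timepoint="WS", tms_type="CSE")
        recs = [r for _ in range(50)
                for r in simulate_mep(TrialSpec(**base), params, rng)]
        assert all(r["rms_pre"] > 0.025 for r in recs)


class TestReproducibility:
    def test_cohort_bit_identical_for_fixed_seed(self, reduced_design):
        cfg = CohortConfig(design=reduced_design)
        a_t, a_m = simulate_cohort(2, cfg, rng_seed=77)
        b_t, b_m = simulate_cohort(2, cfg, rng_seed=77)
        pd.testing.assert_frame_equal(a_t, b_t)
        pd.testing.assert_frame_equal(a_m, b_m)

    def test_invalid_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)

    def test_subject_params_validation(self):
        with pytest.raises(ValueError):
            SubjectParams(go_sigma=-1.0)
        with pytest.raises(ValueError):
            SubjectParams(p_omission=1.5)
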