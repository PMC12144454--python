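"""Schedule layout, staircase dynamics, response model, and eye-trace synthesis."""

import numpy as np
import pytest
from scipy.special import ndtr

import pursuitcal as pc
from pursuitcal.experiment_sim import (EXPOSURE, LEFT, RIGHT, TEST,
                                       head_centric_background_velocity,
                                       staircase_reversal_velocities)

from conftest import run_staircase_track


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


class TestSchedule:
    def test_default_design_counts(self, design):
        trials = pc.build_session_schedule(design)
        sessions = {t.session_id for t in trials}
        exposure_sessions = {t.session_id for t in trials
                             if t.trial_type == EXPOSURE}
        assert len(trials) == 1380
        assert len(sessions) == 9
        assert len(exposure_sessions) == 6
        # control sessions are completed first
        first = [t.condition for t in trials[:3 * design.n_test_per_session]]
        assert set(first) == {pc.CONTROL}

    def test_no_exposure_trials_design(self):
        # 9 sessions of 60 test trials each once exposure trials are removed
        design = pc.DesignConfig(n_exposure_per_session=0)
        trials = pc.build_session_schedule(design)
        assert len(trials) == 540
        assert all(t.trial_type == TEST for t in trials)

    def test_exposure_trial_invariants(self, design):
        trials = pc.build_session_schedule(design)
        for t in trials:
            if t.trial_type == EXPOSURE:
                assert t.pursuit_speed == design.exposure_speed
                expected = (design.exposure_velocity
                            if t.condition == pc.RS_HIGH
                            else -design.exposure_velocity)
                assert t.background_velocity == expected
                assert t.condition in (pc.RS_HIGH, pc.RS_LOW)
        # test trials within one session share one pursuit speed
        for sid in {t.session_id for t in trials}:
            speeds = {t.pursuit_speed for t in trials
                      if t.session_id == sid and t.trial_type == TEST}
            assert len(speeds) == 1

    def test_directions_balanced_within_session(self, design):
        trials = pc.build_session_schedule(design)
        for sid in {t.session_id for t in trials}:
            dirs = [t.pursuit_direction for t in trials
                    if t.session_id == sid]
            assert abs(dirs.count(LEFT) - dirs.count(RIGHT)) <= 1

    @pytest.mark.parametrize("kwargs", [
        {"test_speeds": ()},
        {"test_speeds": (5.5, -1.0)},
        {"n_test_per_session": 0},
        {"n_test_per_session": 61},
        {"background_onset": 2300.0},   # window exits the trajectory
        {"conditions": ("control", "bogus")},
    ])
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(pc.ConfigError):
            pc.DesignConfig(**kwargs)


# ---------------------------------------------------------------------------
# Staircase
# ---------------------------------------------------------------------------


class TestStaircase:
    def test_single_steps(self):
        s = pc.StaircaseState(current_velocity=5.0)
        assert pc.staircase_update(s, pc.WITH_PURSUIT).current_velocity == 4.0
        z = pc.StaircaseState(current_velocity=0.0)
        assert pc.staircase_update(
            z, pc.AGAINST_PURSUIT).current_velocity == 1.0

    def test_alternating_responses_oscillate(self):
        # hand enumeration: 5 -W-> 4 -A-> 5 -W-> 4 ...
        s = pc.StaircaseState(current_velocity=5.0)
        seen = []
        for i in range(8):
            resp = pc.WITH_PURSUIT if i % 2 == 0 else pc.AGAINST_PURSUIT
            s = pc.staircase_update(s, resp)
            seen.append(s.current_velocity)
        assert seen == [4.0, 5.0, 4.0, 5.0, 4.0, 5.0, 4.0, 5.0]

    def test_step_size_invariant(self, rng):
        s = pc.StaircaseState(current_velocity=2.0, step=1.0)
        for _ in range(50):
            resp = rng.choice([pc.WITH_PURSUIT, pc.AGAINST_PURSUIT])
            nxt = pc.staircase_update(s, resp)
            if nxt.n_clamped == s.n_clamped:
                assert abs(nxt.current_velocity - s.current_velocity) == s.step
            s = nxt

    def test_none_response_rejected(self):
        s = pc.StaircaseState(current_velocity=5.0)
        with pytest.raises(pc.ParameterError):
            pc.staircase_update(s, pc.NO_RESPONSE)

    def test_clamping_at_bound(self):
        s = pc.StaircaseState(current_velocity=12.0, bound=12.0)
        s2 = pc.staircase_update(s, pc.AGAINST_PURSUIT)
        assert s2.current_velocity == 12.0
        assert s2.n_clamped == 1

    @pytest.mark.parametrize("n,tol", [(60, 0.5), (2000, 0.1)])
    def test_reversal_mean_converges_to_generative_pss(self, n, tol):
        obs = pc.ObserverParams(gain=0.8, sigma=2.0, lapse=0.01)
        pss = pc.generative_pss(obs, pc.RS_HIGH, 8.5)  # (1-0.8)*8.5 = 1.7
        rng = np.random.default_rng(42)
        state = run_staircase_track(obs, 8.5, n, rng)
        reversals = staircase_reversal_velocities(state.history)
        assert len(reversals) > n / 10
        assert abs(reversals.mean() - pss) < tol


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------


class TestResponseModel:
    @pytest.mark.parametrize("gain,shift,speed,v", [
        (1.0, 0.0, 8.5, 0.0),        # calibrated observer, null stimulus
        (0.76, 0.0, 11.5, 2.76),     # v equals the generative PSS
        (1.0, -1.94, 8.5, -1.94),    # shift-mechanism stationarity point
    ])
    def test_probability_half_at_generative_pss(self, gain, shift, speed, v):
        obs = pc.ObserverParams(gain=gain, shift=shift, sigma=2.0, lapse=0.0)
        p = pc.response_probability(obs, pc.RS_HIGH, speed, v)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_empirical_rate_matches_definition(self, rng):
        obs = pc.ObserverParams(gain=0.8, shift=0.5, sigma=2.0, lapse=0.04)
        trial = pc.TrialRecord("o", "s", pc.RS_HIGH, TEST, 8.5, RIGHT,
                               background_velocity=1.0)
        n = 10_000
        hits = sum(pc.simulate_response(obs, trial, rng) == pc.WITH_PURSUIT
                   for _ in range(n))
        pss = (1 - 0.8) * 8.5 + 0.5
        p = 0.04 / 2 + (1 - 0.04) * ndtr((1.0 - pss) / 2.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_rejects_exposure_trials_and_bad_sigma(self, rng):
        trial = pc.TrialRecord("o", "s", pc.RS_HIGH, EXPOSURE, 8.5, RIGHT,
                               background_velocity=5.0)
        with pytest.raises(pc.ParameterError):
            pc.simulate_response(pc.ObserverParams(), trial, rng)
        with pytest.raises(pc.ParameterError):
            pc.ObserverParams(sigma=0.0)


# ---------------------------------------------------------------------------
# Eye traces
# ---------------------------------------------------------------------------


def _noiseless_observer(oculomotor_gain=1.0):
    return pc.ObserverParams(oculomotor_gain=oculomotor_gain,
                             saccade_rate=0.0, blink_prob=0.0,
                             position_noise_sd=0.0)


def _test_trial(speed=8.5, direction=RIGHT):
    return pc.TrialRecord("o", "s", pc.CONTROL, TEST, speed, direction,
                          background_velocity=0.0, trial_index=0)


class TestEyeTraces:
    def test_ideal_tracking_velocity_equals_target(self, design, rng):
        trace, events = pc.synthesize_eye_trace(_test_trial(),
                                                _noiseless_observer(), rng)
        assert events == []
        lo, hi = trace.background_window(design)
        sel = (trace.t >= lo) & (trace.t < hi)
        v = np.diff(trace.x) / 0.001
        vt = np.diff(trace.target_x) / 0.001
        assert np.allclose(v[sel[:-1]], vt[sel[:-1]], atol=1e-9)

    def test_oculomotor_gain_scales_velocity(self, design, rng):
        trace, _ = pc.synthesize_eye_trace(
            _test_trial(), _noiseless_observer(0.941), rng)
        lo, hi = trace.background_window(design)
        sel = (trace.t >= lo) & (trace.t < hi)
        v = np.diff(trace.x)[sel[:-1]] / 0.001
        assert np.mean(v) == pytest.approx(0.941 * 8.5, abs=0.05)

    def test_trace_invariants_and_ground_truth(self, design):
        rng = np.random.default_rng(5)
        obs = pc.ObserverParams(saccade_rate=2.0, blink_prob=1.0)
        trial = _test_trial(direction=LEFT)
        trace, events = pc.synthesize_eye_trace(trial, obs, rng)
        assert np.allclose(np.diff(trace.t), 1.0)
        assert len(trace.t) == len(trace.x) == len(trace.valid) \
            == len(trace.target_x)
        kinds = {e["event_type"] for e in events}
        assert "saccade" in kinds and "blink" in kinds
        for ev in events:
            assert trace.motion_onset_ms <= ev["onset_ms"]
            assert ev["offset_ms"] <= trace.t[-1] + 1
        # blink gaps are contiguous invalid runs matching the logged blink
        blink = next(e for e in events if e["event_type"] == "blink")
        inv = np.flatnonzero(~trace.valid)
        assert np.all(np.diff(inv) == 1)
        assert inv[0] == int(blink["onset_ms"])

    def test_left_and_right_pursuit_are_mirror_images(self, design):
        obs = _noiseless_observer()
        tr_r, _ = pc.synthesize_eye_trace(_test_trial(direction=RIGHT), obs,
                                          np.random.default_rng(3))
        tr_l, _ = pc.synthesize_eye_trace(_test_trial(direction=LEFT), obs,
                                          np.random.default_rng(3))
        assert np.allclose(tr_r.target_x, -tr_l.target_x)

    def test_head_centric_conversion(self):
        t = _test_trial(direction=LEFT)
        t.background_velocity = 3.0  # with pursuit, i.e. leftward
        assert head_centric_background_velocity(t) == -3.0


# ---------------------------------------------------------------------------
# Closed-loop experiment
# ---------------------------------------------------------------------------


class TestFullSimulation:
    def test_fixed_seed_is_byte_identical(self, design):
        obs = pc.ObserverParams(gain=0.9)
        out = []
        for _ in range(2):
            trials, _, _ = pc.run_simulated_experiment(design, obs, seed=3)
            out.append(pc.trials_to_frame(trials).to_csv(index=False))
        assert out[0] == out[1]

    def test_all_test_trials_answered_and_staircase_driven(self, design):
        obs = pc.ObserverParams()
        trials, _, _ = pc.run_simulated_experiment(design, obs, seed=2)
        for t in trials:
            if t.trial_type == TEST:
                assert t.response in (pc.WITH_PURSUIT, pc.AGAINST_PURSUIT)
                assert t.background_velocity is not None
                assert abs(t.background_velocity) <= design.staircase_bound
            else:
                assert t.response == pc.NO_RESPONSE

    def test_calibrated_observer_recovers_zero_pss(self, calibrated_run):
        # no-exposure measurement: 60 trials per speed in the control cells
        _, trials = calibrated_run
        fits = pc.fit_cells(trials)
        control = fits[fits.condition == pc.CONTROL]
        assert len(control) == 3
        assert (control["pss"].abs() < 0.2).all()

    def test_gain_mechanism_pss_increases_with_speed(self, gain_mechanism_run):
        _, trials = gain_mechanism_run
        fits = pc.fit_cells(trials)
        high = fits[fits.condition == pc.RS_HIGH].sort_values("pursuit_speed")
        assert high["pss"].is_monotonic_increasing

    def test_trial_table_roundtrip(self, tmp_path, design):
        obs = pc.ObserverParams()
        trials, _, _ = pc.run_simulated_experiment(design, obs, seed=4)
        path = tmp_path / "trials.csv"
        pc.write_trial_table(trials, path)
        back = pc.read_trial_table(path)
        assert pc.trials_to_frame(back).equals(pc.trials_to_frame(trials))
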