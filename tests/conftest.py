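import numpy as np
import pytest

import pursuitcal as pc


@pytest.fixture(scope="session")
def design():
    return pc.DesignConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def calibrated_run(design):
    """Well-calibrated observer (gain 1, shift 0, low noise): PSS should be 0."""
    obs = pc.ObserverParams(gain=1.0, shift=0.0, sigma=0.5, lapse=0.0)
    trials, _, _ = pc.run_simulated_experiment(design, obs, seed=7)
    return obs, trials


@pytest.fixture(scope="session")
def gain_mechanism_run(design):
    """Under-compensating observer (gain 0.76): PSS grows with pursuit speed.

    Sensory noise is kept low (sigma 1) so the 0.72 deg/s generative PSS
    steps between adjacent speeds dominate the fit noise at 60 trials/cell.
    """
    obs = pc.ObserverParams(gain=0.76, shift=0.0, sigma=1.0)
    trials, _, _ = pc.run_simulated_experiment(design, obs, seed=11)
    return obs, trials


def run_staircase_track(obs, speed, n_trials, rng, start=5.0,
                        condition=pc.RS_HIGH):
    """Drive a single 1-up/1-down track against a generative observer."""
    state = pc.StaircaseState(current_velocity=start)
    for _ in range(n_trials):
        trial = pc.TrialRecord(
            observer_id="obs", session_id="s", condition=condition,
            trial_type=pc.TEST, pursuit_speed=speed,
            pursuit_direction=pc.experiment_sim.RIGHT,
            background_velocity=state.current_velocity)
        resp = pc.simulate_response(obs, trial, rng)
        state = pc.staircase_update(state, resp)
    return state
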