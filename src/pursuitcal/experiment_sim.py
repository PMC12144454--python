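"""Synthetic smooth-pursuit stationarity experiment.

During smooth pursuit the retinal image of a stationary surround moves
opposite to the eye (reafference).  The experiment simulated here probes how
the internal prediction of that reafference recalibrates after exposure to a
background that moves with the pursuit target ("RS high", reference signal
too high) or against it ("RS low", reference signal too low).  An observer
completes 9 sessions: 3 control sessions (test trials only) followed by
2 exposure conditions x 3 test pursuit speeds.  Exposure sessions interleave
140 exposure trials (pursuit at 8.5 deg/s, background at +/-5 deg/s) with
60 test trials whose background velocity is driven by a 1-up/1-down
staircase, totalling 1,380 trials.

Generative observers answer test trials through a cumulative-Gaussian
decision rule around their generative point of subjective stationarity
(PSS):

    PSS_gen = (1 - gain) * pursuit_speed + shift

so a multiplicative-gain mechanism (gain != 1, shift = 0) produces a PSS
proportional to pursuit speed while a constant-shift mechanism (gain = 1,
shift != 0) produces a speed-independent PSS.  1 kHz horizontal eye traces
with imperfect pursuit gain, catch-up saccades and blinks are synthesised so
the preprocessing stage can be tested against a ground-truth event log.

All background velocities are stored pursuit-relative: positive means the
background moved in the same direction as the pursuit target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

# ---------------------------------------------------------------------------
# Constants & errors
# ---------------------------------------------------------------------------

CONTROL = "control"
RS_HIGH = "RS_high"
RS_LOW = "RS_low"
CONDITIONS = (CONTROL, RS_HIGH, RS_LOW)

EXPOSURE = "exposure"
TEST = "test"

WITH_PURSUIT = "with_pursuit"
AGAINST_PURSUIT = "against_pursuit"
NO_RESPONSE = "none"

LEFT = "left"
RIGHT = "right"

#: screen-axis sign of each pursuit direction (rightward positive)
DIRECTION_SIGN = {LEFT: -1.0, RIGHT: 1.0}


class ConfigError(ValueError):
    """Invalid experiment design configuration."""


class ParameterError(ValueError):
    """Invalid observer parameter or trial state."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """Session/trial layout of the stationarity-recalibration experiment.

    Defaults reproduce the 9-session design: three pursuit test speeds,
    exposure always at 8.5 deg/s with a +/-5 deg/s background, 140 exposure
    + 60 staircase test trials per exposure session, and a 200 ms background
    window opening 1100 ms after motion onset.  The pursuit target travels a
    constant 2400 ms at every speed (eccentricity scales with speed).
    """

    test_speeds: tuple[float, ...] = (5.5, 8.5, 11.5)
    exposure_speed: float = 8.5
    exposure_velocity: float = 5.0
    n_exposure_per_session: int = 140
    n_test_per_session: int = 60
    conditions: tuple[str, ...] = CONDITIONS
    staircase_start: float = 5.0
    staircase_step: float = 1.0
    staircase_bound: float = 12.0
    background_onset: float = 1100.0      # ms after motion onset
    background_duration: float = 200.0    # ms
    fixation_delay_range: tuple[float, float] = (500.0, 1000.0)
    sample_rate: float = 1000.0           # Hz
    ramp_duration: float = 2400.0         # ms of target motion

    def __post_init__(self) -> None:
        if not self.test_speeds or any(s <= 0 for s in self.test_speeds):
            raise ConfigError("test_speeds must be non-empty and positive")
        if self.exposure_speed <= 0:
            raise ConfigError("exposure_speed must be positive")
        if self.n_exposure_per_session < 0 or self.n_test_per_session <= 0:
            raise ConfigError("trial counts must be non-negative (test > 0)")
        if self.n_test_per_session % 2:
            raise ConfigError("n_test_per_session must be even "
                              "(two interleaved staircase tracks)")
        if self.staircase_step <= 0 or self.staircase_start < 0:
            raise ConfigError("staircase_start/step must be valid")
        lo, hi = self.background_window
        if lo < 0 or hi > self.ramp_duration:
            raise ConfigError("background window must lie inside the target "
                              "trajectory")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigError(f"unknown conditions: {sorted(unknown)}")

    @property
    def background_window(self) -> tuple[float, float]:
        """(start, end) of the background presentation, ms after motion onset."""
        return (self.background_onset,
                self.background_onset + self.background_duration)

    @property
    def exposure_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != CONTROL)


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer: recalibration mechanism plus response/eye noise.

    ``gain`` and ``shift`` define the generative PSS in exposure conditions
    via ``(1 - gain) * speed + shift``; the control condition is always
    simulated as perfectly calibrated (gain 1, shift 0) unless overridden by
    ``per_condition``.  ``sigma`` is the SD of the cumulative-Gaussian
    decision rule and therefore corresponds to the JND; ``lapse`` is the
    stimulus-independent error probability.  The oculomotor fields shape the
    synthetic eye traces only.
    """

    gain: float = 1.0
    shift: float = 0.0                 # deg/s, pursuit-relative
    sigma: float = 2.0                 # deg/s
    lapse: float = 0.01
    oculomotor_gain: float = 0.95      # eye velocity / target velocity
    saccade_rate: float = 0.7          # catch-up saccades per second
    blink_prob: float = 0.05           # per-trial blink probability
    position_noise_sd: float = 0.005   # deg, per-sample gaze noise
    per_condition: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if not 0 <= self.lapse < 0.5:
            raise ParameterError("lapse must lie in [0, 0.5)")
        if not 0.8 < self.oculomotor_gain <= 1.1:
            raise ParameterError("oculomotor_gain must lie in (0.8, 1.1]")
        if self.saccade_rate < 0 or not 0 <= self.blink_prob <= 1:
            raise ParameterError("invalid oculomotor event rates")

    def mechanism(self, condition: str) -> tuple[float, float]:
        """(gain, shift) generating the PSS in ``condition``."""
        if self.per_condition and condition in self.per_condition:
            g, c = self.per_condition[condition]
            return float(g), float(c)
        if condition == CONTROL:
            return 1.0, 0.0
        return self.gain, self.shift


def generative_pss(obs: ObserverParams, condition: str,
                   pursuit_speed: float) -> float:
    """Background velocity the observer perceives as stationary."""
    g, c = obs.mechanism(condition)
    return (1.0 - g) * pursuit_speed + c


@dataclass
class TrialRecord:
    """One trial in pursuit-relative sign convention."""

    observer_id: str
    session_id: str
    condition: str
    trial_type: str                       # exposure | test
    pursuit_speed: float                  # unsigned magnitude, deg/s
    pursuit_direction: str                # left | right
    background_velocity: float | None = None  # signed, pursuit-relative
    response: str = NO_RESPONSE
    excluded: bool = False
    seed_tag: str = ""
    trial_index: int = -1                 # position within session

    @property
    def trial_key(self) -> str:
        return f"{self.observer_id}/{self.session_id}/{self.trial_index:03d}"

    @property
    def direction_sign(self) -> float:
        return DIRECTION_SIGN[self.pursuit_direction]


@dataclass(frozen=True)
class StaircaseState:
    """One 1-up/1-down track stepping the background velocity toward the PSS."""

    current_velocity: float
    step: float = 1.0
    bound: float = 12.0
    track_id: int = 0
    history: tuple[tuple[float, str], ...] = ()
    n_clamped: int = 0


def staircase_update(state: StaircaseState, response: str) -> StaircaseState:
    """Step the staircase after a response.

    A ``with_pursuit`` judgement means the background still appeared to move
    in the pursuit direction, so its velocity is decreased by one step;
    ``against_pursuit`` increases it.  Velocities are clamped to
    ``+/-state.bound`` (clamp events are counted in ``n_clamped``).
    """
    if response not in (WITH_PURSUIT, AGAINST_PURSUIT):
        raise ParameterError(f"staircase cannot update on response "
                             f"{response!r}")
    delta = -state.step if response == WITH_PURSUIT else state.step
    v = state.current_velocity + delta
    clamped = abs(v) > state.bound
    if clamped:
        v = float(np.clip(v, -state.bound, state.bound))
    return replace(
        state,
        current_velocity=v,
        history=state.history + ((state.current_velocity, response),),
        n_clamped=state.n_clamped + int(clamped),
    )


def staircase_reversal_velocities(
        history: Sequence[tuple[float, str]]) -> np.ndarray:
    """Stimulus velocities at which the response flipped from the previous one."""
    out = [v for (v, r), (_, rp) in zip(history[1:], history[:-1]) if r != rp]
    return np.asarray(out, dtype=float)


@dataclass
class EyeTrace:
    """1 kHz horizontal gaze record for one trial (blink gaps invalid)."""

    t: np.ndarray                 # ms, strictly increasing at 1 ms
    x: np.ndarray                 # deg, gaze position
    valid: np.ndarray             # bool, False inside blinks
    target_x: np.ndarray          # deg, target position
    trial_key: str
    motion_onset_ms: float = 0.0  # target motion onset in trace time
    pursuit_speed: float = 0.0
    pursuit_direction: str = RIGHT

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.valid) == len(self.target_x) == n):
            raise ValueError("EyeTrace arrays must have equal length")

    def background_window(self, design: DesignConfig) -> tuple[float, float]:
        """Background presentation window in trace time (ms)."""
        lo, hi = design.background_window
        return (self.motion_onset_ms + lo, self.motion_onset_ms + hi)


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def _session_id(condition: str, speed: float) -> str:
    return f"{condition}_{speed:g}"


def build_session_schedule(design: DesignConfig, observer_id: str = "obs00",
                           rng: np.random.Generator | None = None
                           ) -> list[TrialRecord]:
    """Lay out all sessions and trials for one observer (responses unset).

    Control sessions (test trials only) come first; exposure sessions follow
    in an rng-shuffled order, each randomly interleaving exposure and test
    trials.  Pursuit directions are balanced within session.  Test-trial
    background velocities are filled in later by the staircase.
    """
    if rng is None:
        rng = np.random.default_rng(0)

    sessions: list[tuple[str, float]] = []
    if CONTROL in design.conditions:
        sessions.extend((CONTROL, s) for s in design.test_speeds)
    exposure_sessions = [(c, s) for c in design.exposure_conditions
                         for s in design.test_speeds]
    order = rng.permutation(len(exposure_sessions))
    sessions.extend(exposure_sessions[i] for i in order)

    trials: list[TrialRecord] = []
    for condition, speed in sessions:
        sid = _session_id(condition, speed)
        n_exp = design.n_exposure_per_session if condition != CONTROL else 0
        n_test = design.n_test_per_session
        types = np.array([EXPOSURE] * n_exp + [TEST] * n_test)
        rng.shuffle(types)
        n_total = n_exp + n_test
        dirs = np.array([LEFT, RIGHT] * (n_total // 2 + 1))[:n_total]
        rng.shuffle(dirs)
        bg_exposure = (design.exposure_velocity if condition == RS_HIGH
                       else -design.exposure_velocity)
        for i, (tt, d) in enumerate(zip(types, dirs)):
            is_exp = tt == EXPOSURE
            trials.append(TrialRecord(
                observer_id=observer_id,
                session_id=sid,
                condition=condition,
                trial_type=str(tt),
                pursuit_speed=design.exposure_speed if is_exp else speed,
                pursuit_direction=str(d),
                background_velocity=bg_exposure if is_exp else None,
                trial_index=i,
            ))
    return trials


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------


def response_probability(obs: ObserverParams, condition: str,
                         pursuit_speed: float,
                         background_velocity: float) -> float:
    """P(report "with pursuit") under the generative decision rule.

    ``lapse/2 + (1 - lapse) * Phi((v - PSS_gen) / sigma)`` with
    ``PSS_gen = (1 - gain) * speed + shift``.
    """
    pss = generative_pss(obs, condition, pursuit_speed)
    z = (background_velocity - pss) / obs.sigma
    return obs.lapse / 2.0 + (1.0 - obs.lapse) * float(ndtr(z))


def simulate_response(obs: ObserverParams, trial: TrialRecord,
                      rng: np.random.Generator) -> str:
    """Draw a direction judgement for a test trial."""
    if obs.sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if trial.trial_type != TEST or trial.background_velocity is None:
        raise ParameterError("responses are simulated only for test trials "
                             "with a set background velocity")
    p = response_probability(obs, trial.condition, trial.pursuit_speed,
                             trial.background_velocity)
    return WITH_PURSUIT if rng.random() < p else AGAINST_PURSUIT


# ---------------------------------------------------------------------------
# Eye traces
# ---------------------------------------------------------------------------

SACCADE_DURATION_MS = 30.0
#: SD of the Gaussian saccadic velocity pulse; duration/6 keeps the pulse
#: essentially contained within SACCADE_DURATION_MS
_SACCADE_SIGMA_MS = SACCADE_DURATION_MS / 6.0
SACCADE_AMPLITUDE_RANGE = (0.5, 2.0)   # deg
BLINK_DURATION_RANGE = (100.0, 300.0)  # ms


def head_centric_background_velocity(trial: TrialRecord) -> float:
    """Screen-axis background velocity (deg/s, rightward positive)."""
    if trial.background_velocity is None:
        raise ParameterError("trial has no background velocity")
    return trial.direction_sign * trial.background_velocity


def synthesize_eye_trace(trial: TrialRecord, obs: ObserverParams,
                         rng: np.random.Generator,
                         design: DesignConfig | None = None
                         ) -> tuple[EyeTrace, list[dict]]:
    """Generate a 1 kHz gaze trace plus a ground-truth event log.

    The target steps from rest to constant velocity after a random fixation
    delay; the gaze follows at ``oculomotor_gain`` times the target velocity
    with additive Gaussian position noise.  Catch-up saccades are placed by
    a Poisson process (Gaussian velocity pulses of 30 ms, amplitude drawn
    from ``SACCADE_AMPLITUDE_RANGE`` in the direction of pursuit) and blinks
    are contiguous invalid runs of 100-300 ms.  Every injected event is
    returned in the log for detector validation.
    """
    if design is None:
        design = DesignConfig()
    dt = 1000.0 / design.sample_rate  # ms
    delay = float(np.round(rng.uniform(*design.fixation_delay_range)))
    dur = design.ramp_duration
    n = int(round((delay + dur) / dt)) + 1
    t = np.arange(n) * dt
    d = trial.direction_sign
    speed = trial.pursuit_speed
    ecc = speed * dur / 2000.0  # deg; trajectory is symmetric about 0

    motion = np.clip(t - delay, 0.0, dur)
    target_x = -d * ecc + d * speed * motion / 1000.0
    x = -d * ecc + d * obs.oculomotor_gain * speed * motion / 1000.0

    events: list[dict] = []
    n_sac = rng.poisson(obs.saccade_rate * dur / 1000.0)
    onsets: list[float] = []
    for _ in range(n_sac):
        for _attempt in range(50):
            onset = float(np.round(rng.uniform(
                delay, delay + dur - SACCADE_DURATION_MS)))
            if all(abs(onset - o) > 2 * SACCADE_DURATION_MS for o in onsets):
                onsets.append(onset)
                break
    for onset in sorted(onsets):
        amp = d * rng.uniform(*SACCADE_AMPLITUDE_RANGE)
        center = onset + SACCADE_DURATION_MS / 2.0
        x = x + amp * ndtr((t - center) / _SACCADE_SIGMA_MS)
        events.append({"trial_key": trial.trial_key, "event_type": "saccade",
                       "onset_ms": onset,
                       "offset_ms": onset + SACCADE_DURATION_MS})

    valid = np.ones(n, dtype=bool)
    if rng.random() < obs.blink_prob:
        bdur = float(np.round(rng.uniform(*BLINK_DURATION_RANGE)))
        bstart = float(np.round(rng.uniform(delay, delay + dur - bdur)))
        i0, i1 = int(bstart / dt), int((bstart + bdur) / dt)
        valid[i0:i1] = False
        events.append({"trial_key": trial.trial_key, "event_type": "blink",
                       "onset_ms": bstart, "offset_ms": bstart + bdur})

    if obs.position_noise_sd > 0:
        x = x + rng.normal(0.0, obs.position_noise_sd, n)

    trace = EyeTrace(t=t, x=x, valid=valid, target_x=target_x,
                     trial_key=trial.trial_key, motion_onset_ms=delay,
                     pursuit_speed=speed,
                     pursuit_direction=trial.pursuit_direction)
    return trace, events


# ---------------------------------------------------------------------------
# Full closed-loop simulation
# ---------------------------------------------------------------------------


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Named child RNG stream off the root seed (reproducible substreams)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def run_simulated_experiment(design: DesignConfig, obs: ObserverParams,
                             seed: int, observer_id: str = "obs00",
                             observer_index: int = 0,
                             synthesize_traces: bool = False,
                             traces_for: str = TEST
                             ) -> tuple[list[TrialRecord],
                                        dict[str, EyeTrace], list[dict]]:
    """Simulate the full experiment for one observer.

    Runs the schedule, drives two interleaved 1-up/1-down staircase tracks
    per session (starting at +start and -start), draws responses from the
    generative model and optionally synthesises eye traces (for test trials
    by default, or all trials with ``traces_for='all'``).  Output is
    deterministic for a fixed ``(seed, observer_index)``.
    """
    sched_rng = _stream(seed, observer_index, 0)
    trials = build_session_schedule(design, observer_id, rng=sched_rng)

    traces: dict[str, EyeTrace] = {}
    ground_truth: list[dict] = []
    by_session: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        by_session.setdefault(tr.session_id, []).append(tr)

    for k, (sid, sess_trials) in enumerate(by_session.items()):
        rng = _stream(seed, observer_index, k + 1)
        tag = f"{seed}:{observer_index}:{k + 1}"
        tracks = [
            StaircaseState(current_velocity=design.staircase_start,
                           step=design.staircase_step,
                           bound=design.staircase_bound, track_id=0),
            StaircaseState(current_velocity=-design.staircase_start,
                           step=design.staircase_step,
                           bound=design.staircase_bound, track_id=1),
        ]
        n_test = sum(tr.trial_type == TEST for tr in sess_trials)
        track_order = np.repeat([0, 1], [n_test - n_test // 2, n_test // 2])
        rng.shuffle(track_order)
        i_test = 0
        for tr in sess_trials:
            tr.seed_tag = tag
            if tr.trial_type == TEST:
                ti = int(track_order[i_test])
                i_test += 1
                tr.background_velocity = tracks[ti].current_velocity
                tr.response = simulate_response(obs, tr, rng)
                tracks[ti] = staircase_update(tracks[ti], tr.response)
            if synthesize_traces and (traces_for == "all"
                                      or tr.trial_type == traces_for):
                trace, ev = synthesize_eye_trace(tr, obs, rng, design)
                traces[tr.trial_key] = trace
                ground_truth.extend(ev)
    return trials, traces, ground_truth


# ---------------------------------------------------------------------------
# I/O: trial tables, eye traces, ground-truth logs
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ["observer_id", "session_id", "trial_index", "condition",
                 "trial_type", "pursuit_speed", "pursuit_direction",
                 "background_velocity", "response", "excluded", "seed_tag"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [{c: getattr(tr, c) for c in TRIAL_COLUMNS} for tr in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        bg = row.background_velocity
        out.append(TrialRecord(
            observer_id=str(row.observer_id), session_id=str(row.session_id),
            condition=str(row.condition), trial_type=str(row.trial_type),
            pursuit_speed=float(row.pursuit_speed),
            pursuit_direction=str(row.pursuit_direction),
            background_velocity=None if pd.isna(bg) else float(bg),
            response=str(row.response), excluded=bool(row.excluded),
            seed_tag=str(row.seed_tag), trial_index=int(row.trial_index)))
    return out


def write_trial_table(trials: Iterable[TrialRecord], path, sep=",") -> None:
    trials_to_frame(trials).to_csv(path, sep=sep, index=False)


def read_trial_table(path, sep=",") -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, sep=sep))


def write_eye_trace(trace: EyeTrace, path) -> None:
    """Per-trial TSV with columns t_ms, x_deg, target_x_deg, valid."""
    pd.DataFrame({"t_ms": trace.t, "x_deg": trace.x,
                  "target_x_deg": trace.target_x,
                  "valid": trace.valid.astype(int)}).to_csv(
        path, sep="\t", index=False)


def read_eye_trace(path, trial_key: str = "") -> EyeTrace:
    """Read a trace TSV; motion onset/speed/direction recovered from target_x."""
    df = pd.read_csv(path, sep="\t")
    t = df["t_ms"].to_numpy(float)
    target = df["target_x_deg"].to_numpy(float)
    moving = np.flatnonzero(np.abs(np.diff(target)) > 1e-12)
    onset = float(t[moving[0]]) if len(moving) else 0.0
    if len(moving):
        dx = target[moving[-1] + 1] - target[moving[0]]
        dt_s = (t[moving[-1] + 1] - t[moving[0]]) / 1000.0
        vel = dx / dt_s
    else:
        vel = 0.0
    return EyeTrace(t=t, x=df["x_deg"].to_numpy(float),
                    valid=df["valid"].to_numpy(bool),
                    target_x=target, trial_key=trial_key,
                    motion_onset_ms=onset, pursuit_speed=abs(vel),
                    pursuit_direction=RIGHT if vel >= 0 else LEFT)


def write_ground_truth(events: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev) + "\n")


def read_ground_truth(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
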