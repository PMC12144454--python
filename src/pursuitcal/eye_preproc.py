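"""Gaze preprocessing: velocity, saccade/blink detection, exclusion, pursuit gain.

Eye velocity is obtained by central differencing of the 1 kHz position
samples over a +/-5 ms window.  Saccades are detected by threshold crossing
on velocity (22 deg/s) or acceleration (3800 deg/s^2) relative to the smooth
pursuit baseline — thresholding must be baseline-relative because pursuit
itself reaches 11.5 deg/s.  Blinks are contiguous invalid-sample runs,
padded before overlap testing because lid artifacts contaminate neighbouring
samples.  Trials in which a saccade or blink overlaps the background
presentation window are excluded from both the psychophysical and the
eye-movement analysis.  Pursuit gain (eye velocity / target velocity) is
computed over the valid, saccade-free samples of that window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .experiment_sim import (DesignConfig, EyeTrace, TrialRecord,
                             DIRECTION_SIGN)

V_THRESH = 22.0        # deg/s, saccade velocity threshold
A_THRESH = 3800.0      # deg/s^2, saccade acceleration threshold
MIN_SACCADE_MS = 8.0   # minimum event duration
MERGE_GAP_MS = 20.0    # merge saccade runs closer than this
MIN_BLINK_MS = 20.0    # minimum invalid run to call a blink
BLINK_PAD_MS = 50.0    # padding applied around blinks before overlap tests
DIFF_WINDOW_MS = 10.0  # full width of the central-difference window


class EmptyVelocityError(ValueError):
    """Trace has too few valid samples to differentiate."""


@dataclass
class VelocityTrace:
    """Eye velocity/acceleration derived from an EyeTrace (NaN where invalid)."""

    t: np.ndarray        # ms
    v: np.ndarray        # deg/s
    a: np.ndarray        # deg/s^2
    valid: np.ndarray    # bool


@dataclass(frozen=True)
class OculomotorEvent:
    kind: str            # saccade | blink
    onset_ms: float
    offset_ms: float

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("event offset must follow onset")

    def overlaps(self, window: tuple[float, float]) -> bool:
        return self.onset_ms < window[1] and self.offset_ms > window[0]


@dataclass(frozen=True)
class PursuitGainRecord:
    trial_key: str
    gain: float          # eye velocity / target velocity; NaN if no samples
    n_samples_used: int


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------


def differentiate(trace: EyeTrace, window_ms: float = DIFF_WINDOW_MS
                  ) -> VelocityTrace:
    """Central-difference velocity over +/-window_ms/2; acceleration as the
    first difference of velocity.  Samples whose stencil touches an invalid
    (blink) sample are themselves invalid.
    """
    x = np.asarray(trace.x, float)
    t = np.asarray(trace.t, float)
    n = len(x)
    if n < 3:
        raise EmptyVelocityError("trace too short to differentiate")
    dt = float(np.median(np.diff(t)))  # ms
    h = max(1, int(round(window_ms / 2.0 / dt)))

    src_valid = np.asarray(trace.valid, bool)
    # longest run of consecutive valid samples must allow one stencil
    if not src_valid.any():
        raise EmptyVelocityError("all samples invalid")
    runs = _bool_runs(src_valid)
    if max(j - i for i, j in runs) < 3:
        raise EmptyVelocityError("fewer than 3 consecutive valid samples")

    v = np.full(n, np.nan)
    v[h:n - h] = (x[2 * h:] - x[:n - 2 * h]) / (2 * h * dt / 1000.0)
    valid = np.zeros(n, dtype=bool)
    # stencil validity: all samples in [i-h, i+h] valid
    kern = np.ones(2 * h + 1)
    ok = np.convolve(src_valid.astype(int), kern, mode="same") == len(kern)
    valid[h:n - h] = ok[h:n - h]
    v[~valid] = np.nan

    a = np.full(n, np.nan)
    a[:-1] = (v[1:] - v[:-1]) / (dt / 1000.0)
    a[~valid] = np.nan
    a[:-1][~valid[1:]] = np.nan
    return VelocityTrace(t=t, v=v, a=a, valid=valid)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    m = np.asarray(mask, bool).astype(int)
    d = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


def detect_saccades(vel: VelocityTrace, v_thresh: float = V_THRESH,
                    a_thresh: float = A_THRESH,
                    min_duration_ms: float = MIN_SACCADE_MS,
                    merge_gap_ms: float = MERGE_GAP_MS,
                    baseline: float | None = None,
                    baseline_window: tuple[float, float] | None = None
                    ) -> list[OculomotorEvent]:
    """Threshold-crossing saccade detection relative to the pursuit baseline.

    A sample belongs to a saccade if |v - baseline| > v_thresh or
    |a| > a_thresh.  The baseline defaults to the median valid velocity
    (optionally restricted to ``baseline_window``, e.g. the 200 ms before
    the background).  Runs separated by less than ``merge_gap_ms`` are
    merged; events shorter than ``min_duration_ms`` are dropped.
    """
    t, v, a, valid = vel.t, vel.v, vel.a, vel.valid
    if baseline is None:
        sel = valid.copy()
        if baseline_window is not None:
            sel &= (t >= baseline_window[0]) & (t < baseline_window[1])
        baseline = float(np.nanmedian(v[sel])) if sel.any() else 0.0

    with np.errstate(invalid="ignore"):
        mask = valid & ((np.abs(v - baseline) > v_thresh)
                        | (np.abs(a) > a_thresh))
    runs = _bool_runs(mask)
    if not runs:
        return []
    dt = float(np.median(np.diff(t)))
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if (i0 - merged[-1][1]) * dt < merge_gap_ms:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    events = []
    for i0, i1 in merged:
        if (i1 - i0) * dt >= min_duration_ms:
            events.append(OculomotorEvent("saccade", float(t[i0]),
                                          float(t[i1 - 1] + dt)))
    return events


def detect_blinks(trace: EyeTrace, min_run_ms: float = MIN_BLINK_MS,
                  pad_ms: float = BLINK_PAD_MS) -> list[OculomotorEvent]:
    """Invalid-sample runs >= min_run_ms, padded by pad_ms on each side."""
    t = np.asarray(trace.t, float)
    dt = float(np.median(np.diff(t)))
    events = []
    for i0, i1 in _bool_runs(~np.asarray(trace.valid, bool)):
        if (i1 - i0) * dt >= min_run_ms:
            events.append(OculomotorEvent(
                "blink", float(t[i0] - pad_ms), float(t[i1 - 1] + dt + pad_ms)))
    return events


def detect_events(trace: EyeTrace, vel: VelocityTrace | None = None,
                  **saccade_kwargs) -> list[OculomotorEvent]:
    """Saccades and blinks for one trace."""
    if vel is None:
        vel = differentiate(trace)
    return detect_saccades(vel, **saccade_kwargs) + detect_blinks(trace)


# ---------------------------------------------------------------------------
# Exclusion and pursuit gain
# ---------------------------------------------------------------------------


def exclude_trials(trials: Sequence[TrialRecord],
                   events_by_trial: Mapping[str, Sequence[OculomotorEvent]],
                   windows: Mapping[str, tuple[float, float]]
                   ) -> list[TrialRecord]:
    """Flag trials whose background window overlaps any saccade or blink.

    The flag feeds both the psychophysical and the eye-movement analysis.
    Trials without an entry in ``windows`` (no trace recorded) keep their
    current flag.  Idempotent: flags depend only on events and windows.
    """
    for tr in trials:
        if tr.trial_key not in windows:
            continue
        win = windows[tr.trial_key]
        evs = events_by_trial.get(tr.trial_key, ())
        tr.excluded = any(ev.overlaps(win) for ev in evs)
    return list(trials)


def pursuit_gain(vel: VelocityTrace, trial: TrialRecord,
                 window: tuple[float, float],
                 saccade_events: Sequence[OculomotorEvent] = ()
                 ) -> PursuitGainRecord:
    """Eye velocity / target velocity over valid, saccade-free window samples.

    The sign convention divides by the signed target velocity so ideal
    tracking yields +1 for either pursuit direction.  With zero usable
    samples the gain is NaN and the trial drops out of gain summaries.
    """
    t = vel.t
    mask = vel.valid & (t >= window[0]) & (t < window[1])
    for ev in saccade_events:
        if ev.kind == "saccade":
            mask &= ~((t >= ev.onset_ms) & (t < ev.offset_ms))
    n_used = int(mask.sum())
    if n_used == 0:
        return PursuitGainRecord(trial.trial_key, float("nan"), 0)
    target_v = DIRECTION_SIGN[trial.pursuit_direction] * trial.pursuit_speed
    gain = float(np.nanmean(vel.v[mask]) / target_v)
    return PursuitGainRecord(trial.trial_key, gain, n_used)


def retinal_speed_difference(gain_difference: float, speed: float) -> float:
    """Retinal-speed difference of a stationary pattern implied by a pursuit
    gain difference: the pattern's retinal speed equals the eye speed, so a
    gain change of dg at target speed s changes it by |dg| * s."""
    return abs(gain_difference) * speed


def retinal_velocity(background_head_centric: float,
                     eye_velocity: float) -> float:
    """Retinal velocity = head-centric background velocity - eye velocity."""
    return background_head_centric - eye_velocity


# ---------------------------------------------------------------------------
# Batch preprocessing
# ---------------------------------------------------------------------------


def preprocess(trials: Sequence[TrialRecord],
               traces: Mapping[str, EyeTrace],
               design: DesignConfig | None = None
               ) -> tuple[list[TrialRecord],
                          dict[str, list[OculomotorEvent]], pd.DataFrame]:
    """Run differentiation, detection, exclusion and gain for a trial set.

    Returns the trials with updated exclusion flags, the per-trial event
    lists, and a pursuit-gain table (one row per non-excluded trial with a
    trace; NaN gain when no usable samples remain).
    """
    if design is None:
        design = DesignConfig()
    events_by_trial: dict[str, list[OculomotorEvent]] = {}
    windows: dict[str, tuple[float, float]] = {}
    vels: dict[str, VelocityTrace] = {}
    for key, trace in traces.items():
        win = trace.background_window(design)
        vel = differentiate(trace)
        events_by_trial[key] = detect_saccades(
            vel, baseline_window=(win[0] - 200.0, win[0])) \
            + detect_blinks(trace)
        windows[key] = win
        vels[key] = vel
    trials = exclude_trials(trials, events_by_trial, windows)
    rows = []
    for tr in trials:
        if tr.trial_key not in traces or tr.excluded:
            continue
        rec = pursuit_gain(vels[tr.trial_key], tr, windows[tr.trial_key],
                           events_by_trial[tr.trial_key])
        rows.append({"trial_key": rec.trial_key,
                     "observer_id": tr.observer_id,
                     "condition": tr.condition,
                     "pursuit_speed": tr.pursuit_speed,
                     "gain": rec.gain,
                     "n_samples_used": rec.n_samples_used})
    gains = pd.DataFrame(rows, columns=["trial_key", "observer_id",
                                        "condition", "pursuit_speed",
                                        "gain", "n_samples_used"])
    return list(trials), events_by_trial, gains


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_events(events_by_trial: Mapping[str, Sequence[OculomotorEvent]],
                 path) -> None:
    """JSON-lines: one record per event (trial_key, kind, onset_ms, offset_ms)."""
    with open(path, "w") as fh:
        for key, evs in events_by_trial.items():
            for ev in evs:
                fh.write(json.dumps({"trial_key": key, "kind": ev.kind,
                                     "onset_ms": ev.onset_ms,
                                     "offset_ms": ev.offset_ms}) + "\n")


def read_events(path) -> dict[str, list[OculomotorEvent]]:
    out: dict[str, list[OculomotorEvent]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.setdefault(rec["trial_key"], []).append(
                OculomotorEvent(rec["kind"], rec["onset_ms"],
                                rec["offset_ms"]))
    return out


def write_gains(gains: pd.DataFrame, path) -> None:
    gains.to_csv(path, index=False)
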