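"""Cumulative-Gaussian psychometric fitting: PSS and JND per condition cell.

Direction judgements (background moved with vs against pursuit) are fit per
observer x condition x pursuit speed with

    P(with_pursuit | v) = lapse/2 + (1 - lapse) * Phi((v - pss) / jnd)

by maximum likelihood.  The 50% point ``pss`` is the point of subjective
stationarity; the Gaussian SD ``jnd`` is the just-noticeable difference.
Staircase data concentrate near the PSS and constrain the asymptotes poorly,
so by default the lapse rate is fixed at a small value; a bounded free-lapse
mode is available.  Left- and right-pursuit trials are merged on the
pursuit-relative velocity axis before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .experiment_sim import TEST, WITH_PURSUIT, AGAINST_PURSUIT, TrialRecord

PSS_BOUNDS = (-12.0, 12.0)
JND_BOUNDS = (0.05, 20.0)
DEFAULT_FIXED_LAPSE = 0.01
LAPSE_MAX = 0.06
#: deterministic multistart grid (pss x jnd)
_STARTS = [(p, j) for p in (-4.0, 0.0, 4.0) for j in (1.0, 4.0)]

_P_CLIP = 1e-9


class DegenerateDataError(ValueError):
    """Responses cannot identify a psychometric function."""


@dataclass(frozen=True)
class ResponseSet:
    """Test-trial responses of one (observer, condition, speed) cell."""

    velocities: np.ndarray          # deg/s, pursuit-relative
    with_pursuit: np.ndarray        # bool
    key: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "velocities",
                           np.asarray(self.velocities, float))
        object.__setattr__(self, "with_pursuit",
                           np.asarray(self.with_pursuit, bool))
        if len(self.velocities) != len(self.with_pursuit):
            raise ValueError("velocities and responses differ in length")

    def __len__(self) -> int:
        return len(self.velocities)


@dataclass(frozen=True)
class PsychometricFit:
    pss: float
    jnd: float
    lapse: float
    loglik: float
    n_trials: int
    converged: bool


def negloglik(pss: float, jnd: float, lapse: float,
              data: ResponseSet) -> float:
    """Negative Bernoulli log-likelihood of the cumulative-Gaussian model."""
    if jnd <= 0:
        raise ValueError("jnd must be > 0")
    if len(data) == 0:
        raise DegenerateDataError("empty response set")
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((data.velocities - pss) / jnd)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    y = data.with_pursuit
    return float(-(np.log(p[y]).sum() + np.log(1.0 - p[~y]).sum()))


def fit_psychometric(data: ResponseSet, lapse_mode: str = "fixed",
                     fixed_lapse: float = DEFAULT_FIXED_LAPSE,
                     lapse_max: float = LAPSE_MAX) -> PsychometricFit:
    """Maximum-likelihood fit from deterministic multistarts.

    ``lapse_mode='fixed'`` holds the lapse at ``fixed_lapse``; ``'free'``
    estimates it within [0, lapse_max].  Requires >= 3 distinct stimulus
    velocities and both response categories; raises DegenerateDataError
    otherwise.  Optimizer non-convergence is reported via ``converged``
    rather than raised, keeping the best point found.
    """
    if len(np.unique(data.velocities)) < 3:
        raise DegenerateDataError(
            f"need >= 3 distinct velocities, got "
            f"{len(np.unique(data.velocities))} (cell {data.key})")
    if data.with_pursuit.all() or (~data.with_pursuit).all():
        raise DegenerateDataError(
            f"responses are all one category (cell {data.key}); "
            f"the psychometric location is unidentified")
    if lapse_mode not in ("fixed", "free"):
        raise ValueError(f"unknown lapse_mode {lapse_mode!r}")
    free_lapse = lapse_mode == "free"

    def objective(theta):
        lapse = theta[2] if free_lapse else fixed_lapse
        return negloglik(theta[0], theta[1], lapse, data)

    bounds = [PSS_BOUNDS, JND_BOUNDS] + ([(0.0, lapse_max)] if free_lapse
                                         else [])
    best = None
    for pss0, jnd0 in _STARTS:
        x0 = [pss0, jnd0] + ([fixed_lapse] if free_lapse else [])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    lapse = float(best.x[2]) if free_lapse else fixed_lapse
    return PsychometricFit(pss=float(best.x[0]), jnd=float(best.x[1]),
                           lapse=lapse, loglik=-float(best.fun),
                           n_trials=len(data), converged=bool(best.success))


def bin_proportions(data: ResponseSet, bin_width: float = 1.0
                    ) -> pd.DataFrame:
    """Proportion of with-pursuit responses per velocity bin (plots only).

    Bins are centred on multiples of ``bin_width``; the returned ``n``
    column sums to the number of trials.
    """
    centers = np.round(data.velocities / bin_width) * bin_width
    df = pd.DataFrame({"velocity_bin": centers,
                       "with_pursuit": data.with_pursuit.astype(float)})
    out = df.groupby("velocity_bin", as_index=False).agg(
        proportion_with_pursuit=("with_pursuit", "mean"),
        n=("with_pursuit", "size"))
    return out


# ---------------------------------------------------------------------------
# Trial-table interface
# ---------------------------------------------------------------------------


def responses_by_cell(trials: Sequence[TrialRecord]
                      ) -> dict[tuple, ResponseSet]:
    """Group non-excluded test trials by (observer, condition, speed)."""
    cells: dict[tuple, list[tuple[float, bool]]] = {}
    for tr in trials:
        if tr.trial_type != TEST or tr.excluded:
            continue
        if tr.response not in (WITH_PURSUIT, AGAINST_PURSUIT):
            continue
        key = (tr.observer_id, tr.condition, tr.pursuit_speed)
        cells.setdefault(key, []).append(
            (tr.background_velocity, tr.response == WITH_PURSUIT))
    return {key: ResponseSet(np.array([v for v, _ in rows]),
                             np.array([y for _, y in rows]), key=key)
            for key, rows in cells.items()}


def fit_cells(trials: Sequence[TrialRecord], lapse_mode: str = "fixed",
              fixed_lapse: float = DEFAULT_FIXED_LAPSE) -> pd.DataFrame:
    """Fit every cell of a trial table; one row per (observer, condition, speed)."""
    rows = []
    for (obs, cond, speed), data in sorted(responses_by_cell(trials).items()):
        fit = fit_psychometric(data, lapse_mode=lapse_mode,
                               fixed_lapse=fixed_lapse)
        rows.append({"observer_id": obs, "condition": cond,
                     "pursuit_speed": speed, "pss": fit.pss, "jnd": fit.jnd,
                     "lapse": fit.lapse, "loglik": fit.loglik,
                     "n_trials": fit.n_trials, "converged": fit.converged})
    return pd.DataFrame(rows, columns=["observer_id", "condition",
                                       "pursuit_speed", "pss", "jnd",
                                       "lapse", "loglik", "n_trials",
                                       "converged"])


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)
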