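"""Gain vs shift models of PSS-versus-speed profiles, compared by BIC weights.

Two one-parameter accounts of how the point of subjective stationarity (PSS)
depends on pursuit speed:

    gain model:   PSS = (1 - gain) * speed     (through-origin line; gain 1 =
                  perfect compensation of self-induced retinal motion,
                  0 = none)
    shift model:  PSS = shift                  (constant recalibration bias)

Both are fit by least squares in closed form.  Model evidence uses

    BIC    = n * ln(RSS / n) + k * ln(n)            (k = 1)
    dBIC_i = BIC_i - min_r BIC_r
    p_i    = exp(-dBIC_i / 2) / sum_r exp(-dBIC_r / 2)

The BIC diverges at RSS = 0, so RSS is floored at ``RSS_FLOOR`` and a model
hitting the floor while its competitor does not receives weight 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GAIN = "gain"
SHIFT = "shift"
TIED = "tied"

RSS_FLOOR = 1e-12  # (deg/s)^2


@dataclass(frozen=True)
class PssProfile:
    """PSS at each pursuit speed for one observer (or the group mean)."""

    speeds: tuple[float, ...]
    pss: tuple[float, ...]
    label: str = "group_mean"
    condition: str = ""

    def __post_init__(self):
        if len(self.speeds) != len(self.pss) or len(self.speeds) < 1:
            raise ValueError("speeds and pss must be equal-length, n >= 1")
        if len(set(self.speeds)) != len(self.speeds):
            raise ValueError("speeds must be distinct")
        if any(s < 0 for s in self.speeds):
            raise ValueError("speeds must be non-negative")


@dataclass(frozen=True)
class ModelFit:
    model: str          # gain | shift
    parameter: float    # gain g (dimensionless) or shift (deg/s)
    rss: float          # (deg/s)^2
    n: int
    k: int
    bic: float
    rss_floored: bool = False


@dataclass(frozen=True)
class ModelWeights:
    weights: Mapping[str, float]
    delta_bic: Mapping[str, float]


def fit_gain_model(profile: PssProfile) -> ModelFit:
    """Closed-form least squares of PSS = (1 - g) * speed through the origin."""
    s = np.asarray(profile.speeds, float)
    y = np.asarray(profile.pss, float)
    denom = float((s ** 2).sum())
    if denom == 0:
        raise ValueError("gain model undefined when all speeds are zero")
    slope = float((s * y).sum()) / denom       # slope = 1 - gain
    rss = float(((y - slope * s) ** 2).sum())
    n = len(s)
    return ModelFit(GAIN, 1.0 - slope, rss, n, 1, bic(rss, n, 1),
                    rss_floored=rss < RSS_FLOOR)


def fit_shift_model(profile: PssProfile) -> ModelFit:
    """Constant-PSS model: parameter is the mean PSS."""
    y = np.asarray(profile.pss, float)
    mean = float(y.mean())
    rss = float(((y - mean) ** 2).sum())
    n = len(y)
    return ModelFit(SHIFT, mean, rss, n, 1, bic(rss, n, 1),
                    rss_floored=rss < RSS_FLOOR)


def bic(rss: float, n: int, k: int = 1) -> float:
    """n * ln(RSS/n) + k * ln(n), with RSS floored at RSS_FLOOR."""
    if n < 1:
        raise ValueError("BIC requires n >= 1")
    if k < 0:
        raise ValueError("BIC requires k >= 0")
    return n * math.log(max(rss, RSS_FLOOR) / n) + k * math.log(n)


def model_weights(bics: Mapping[str, float],
                  floored: Mapping[str, bool] | None = None) -> ModelWeights:
    """Relative evidence p_i = softmax(-BIC_i / 2).

    Invariant to adding a constant to all BICs and to relabelling.  If
    exactly one model's RSS hit the floor (``floored``), it takes weight 1
    outright — the limit of the softmax as its RSS -> 0.
    """
    if len(bics) < 2:
        raise ValueError("need at least two models to compare")
    if any(not math.isfinite(b) for b in bics.values()):
        raise ValueError("non-finite BIC")
    floored = floored or {}
    names = list(bics)
    hit = [m for m in names if floored.get(m)]
    if len(hit) == 1 and len(names) == 2:
        w = {m: (1.0 if m in hit else 0.0) for m in names}
    else:
        b = np.array([bics[m] for m in names])
        d = b - b.min()
        e = np.exp(-0.5 * d)
        w = dict(zip(names, e / e.sum()))
    bmin = min(bics.values())
    return ModelWeights(weights=w,
                        delta_bic={m: bics[m] - bmin for m in names})


def classify_mechanism(weights: ModelWeights,
                       threshold: float = 0.5) -> str:
    """Winning mechanism: the model with weight > threshold, else 'tied'."""
    for model, w in weights.weights.items():
        if w > threshold:
            return model
    return TIED


def compare_models(profile: PssProfile) -> dict:
    """Fit both models to one profile and compute weights + classification."""
    gfit = fit_gain_model(profile)
    sfit = fit_shift_model(profile)
    weights = model_weights({GAIN: gfit.bic, SHIFT: sfit.bic},
                            floored={GAIN: gfit.rss_floored,
                                     SHIFT: sfit.rss_floored})
    return {"label": profile.label, "condition": profile.condition,
            "gain": gfit.parameter, "shift": sfit.parameter,
            "rss_gain": gfit.rss, "rss_shift": sfit.rss,
            "bic_gain": gfit.bic, "bic_shift": sfit.bic,
            "weight_gain": weights.weights[GAIN],
            "weight_shift": weights.weights[SHIFT],
            "classification": classify_mechanism(weights)}


MODEL_COLUMNS = ["label", "condition", "gain", "shift", "rss_gain",
                 "rss_shift", "bic_gain", "bic_shift", "weight_gain",
                 "weight_shift", "classification"]


def profiles_from_fits(fits: pd.DataFrame) -> list[PssProfile]:
    """One profile per (observer, condition) from a psychometric fits table."""
    out = []
    for (obs, cond), grp in fits.groupby(["observer_id", "condition"]):
        grp = grp.sort_values("pursuit_speed")
        out.append(PssProfile(tuple(grp["pursuit_speed"]),
                              tuple(grp["pss"]), label=str(obs),
                              condition=str(cond)))
    return out


def compare_table(fits: pd.DataFrame,
                  classify_conditions: Sequence[str] | None = None
                  ) -> pd.DataFrame:
    """Model comparison for every (observer, condition) profile.

    Control profiles are fit like the others but are reported without a
    mechanism classification (``classify_conditions`` limits which
    conditions get one; default: every condition except 'control').
    """
    rows = []
    for profile in profiles_from_fits(fits):
        row = compare_models(profile)
        if classify_conditions is not None \
                and profile.condition not in classify_conditions:
            row["classification"] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=MODEL_COLUMNS)


def write_models(models: pd.DataFrame, path) -> None:
    models.to_csv(path, index=False)
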