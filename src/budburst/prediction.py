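"""Calendar predictions from fitted transition models.

A fitted model is turned into a population-level transition-probability
curve π(d) over a daily covariate path (random effects at zero), and the
curve is inverted at a probability threshold — 0.51 by default — to give
the predicted day-of-year of the transition.  From the crossing days
follow the budbreak duration (last minus first transition), the heating
requirement (cumulative growing degree-days at the bud-open crossing) and
the frost exposure (fitted frost probability at a crossing).

The crossing is the FIRST upward crossing on the daily grid, located by
linear interpolation between the bracketing days; curves driven by frost
probability need not be monotone in DOY.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import FrostModel, Standardizer
from .glmm import FitResult
from .selection import build_design

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.51


@dataclass
class TransitionCurve:
    """Daily transition probabilities for one group on one covariate path."""

    transition: str
    group_levels: dict
    doy: np.ndarray
    prob: np.ndarray
    covariate_path: pd.DataFrame

    def __post_init__(self):
        d = np.asarray(self.doy)
        if len(d) > 1 and not np.array_equal(np.diff(d), np.ones(len(d) - 1)):
            raise ValueError("curve grid must cover the season daily, without gaps")


@dataclass
class CrossingResult:
    """Threshold crossing of one transition curve with covariates attached."""

    transition: str
    group_levels: dict
    crossing_doy: float | None
    status: str = "ok"                      # ok | no_crossing
    gdd_at_crossing: float = np.nan
    daylength_at_crossing: float = np.nan
    frost_prob_at_crossing: float = np.nan


def transition_curve(
    fit: FitResult,
    covariate_path: pd.DataFrame,
    standardizer: Standardizer,
    group_levels: dict | None = None,
    transition: str = "",
) -> TransitionCurve:
    """Population-level π(d) for one (site, group) over a daily covariate path.

    ``covariate_path`` holds unstandardized columns (doy plus the climate
    variables) on a daily grid; standardization reuses the training
    parameters.  ``group_levels`` fixes the factor levels (e.g. site,
    species) for the prediction; random effects are set to zero.
    """
    group_levels = group_levels or {}
    spec = fit.spec
    if spec is None:
        raise ValueError("fit has no model spec attached")
    path = covariate_path.sort_values("doy").reset_index(drop=True)
    need = spec.effective_variable
    if need not in path.columns:
        raise ValueError(f"covariate path missing column {need!r}")
    frame = path.copy()
    for fct, lev in group_levels.items():
        frame[fct] = lev
    levels = getattr(fit, "levels", None)
    X, _ = build_design(frame, spec, standardizer, levels=levels)
    missing = [c for c in fit.params.index if c not in X.columns]
    if missing:
        raise ValueError(f"prediction design missing terms {missing}")
    eta = X[list(fit.params.index)].to_numpy(dtype=float) @ fit.params.to_numpy()
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return TransitionCurve(
        transition=transition or fit.model_id,
        group_levels=dict(group_levels),
        doy=path["doy"].to_numpy(dtype=float),
        prob=prob,
        covariate_path=path,
    )


def crossing_day(curve: TransitionCurve, threshold: float = DEFAULT_THRESHOLD) -> float | None:
    """DOY of the first upward crossing of ``threshold``, or None.

    Linear interpolation between the bracketing grid days; a curve already
    at/above threshold on its first day crosses there.  None (logged, not
    an error) when the curve never reaches the threshold.
    """
    p = curve.prob
    d = curve.doy
    if p[0] >= threshold:
        return float(d[0])
    above = np.nonzero(p >= threshold)[0]
    if len(above) == 0:
        logger.info("transition %s never reaches %.2f (max %.3f)",
                    curve.transition, threshold, float(p.max()))
        return None
    i = above[0]
    frac = (threshold - p[i - 1]) / (p[i] - p[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def budbreak_duration(first_crossing: float | None,
                      last_crossing: float | None) -> tuple[float | None, str]:
    """Budbreak duration in days: crossing(5→6) − crossing(0→12).

    Returns (duration, status); status is ``"ok"``, ``"undefined"`` when a
    crossing is missing, or ``"ordering_anomaly"`` for a negative duration
    (late transition predicted before an early one — possible because the
    transitions are modelled separately).
    """
    if first_crossing is None or last_crossing is None:
        return None, "undefined"
    dur = float(last_crossing - first_crossing)
    if dur < 0:
        logger.warning("budbreak duration negative (%.1f d): ordering anomaly", dur)
        return dur, "ordering_anomaly"
    return dur, "ok"


def heating_requirement(crossing_doy: float, gdd: pd.DataFrame,
                        which: str = "mean") -> float:
    """Cumulative growing degree-days at the crossing day (interpolated).

    ``gdd`` is a daily frame with columns doy and gdd_mean/gdd_max for one
    (site, year) or an averaged season.
    """
    col = f"gdd_{which}"
    if col not in gdd.columns:
        raise ValueError(f"gdd table lacks column {col!r}")
    g = gdd.sort_values("doy")
    d = g["doy"].to_numpy(dtype=float)
    if not (d[0] <= crossing_doy <= d[-1]):
        raise ValueError(
            f"crossing DOY {crossing_doy} outside GDD coverage [{d[0]}, {d[-1]}]"
        )
    return float(np.interp(crossing_doy, d, g[col].to_numpy(dtype=float)))


def frost_exposure(frost_model: FrostModel, doy: float) -> float:
    """Fitted daily frost probability at a DOY (clamped if degenerate)."""
    return float(frost_model.predict(doy))


def predict_crossings(
    fit: FitResult,
    covariate_path: pd.DataFrame,
    standardizer: Standardizer,
    group_levels: dict,
    frost_model: FrostModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    transition: str = "",
) -> CrossingResult:
    """Crossing day for one (transition, group) with covariates evaluated there."""
    curve = transition_curve(fit, covariate_path, standardizer, group_levels,
                             transition=transition)
    doy = crossing_day(curve, threshold)
    if doy is None:
        return CrossingResult(transition, dict(group_levels), None, "no_crossing")
    res = CrossingResult(transition, dict(group_levels), doy)
    path = curve.covariate_path
    d = path["doy"].to_numpy(dtype=float)
    if "gdd_mean" in path.columns:
        res.gdd_at_crossing = float(np.interp(doy, d, path["gdd_mean"]))
    if "day_length" in path.columns:
        res.daylength_at_crossing = float(np.interp(doy, d, path["day_length"]))
    if frost_model is not None:
        res.frost_prob_at_crossing = frost_exposure(frost_model, doy)
    elif "frost_prob" in path.columns:
        res.frost_prob_at_crossing = float(np.interp(doy, d, path["frost_prob"]))
    return res
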