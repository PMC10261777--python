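"""Least-squares estimation of rehydration-model parameters and fit statistics.

Each fit minimises the sum of squared residuals between observed and
predicted dry-basis moisture.  The initial moisture Xw0 is always fixed
at the measured t = 0 value, never fitted, so the parameter counts are
Z = 2 (Peleg), Z = 3 (Weibull) and Z = 2 (logarithmic model).

Goodness of fit follows the usual thin-layer conventions:

    RMSE = sqrt( SSE / N )
    reduced chi-square = SSE / (N - Z)
    R^2 = 1 - SSE / sum((obs - mean(obs))^2)

Residuals are computed on moisture content directly by default; set
``residual_on="moisture_ratio"`` to compute the statistics on the
normalised moisture ratio (X - Xw0) / (X_last - Xw0) instead.  The
normalisation is affine, so it changes the reported statistics but not
the least-squares parameter estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .kinetics_models import (
    PelegParams,
    ProposedParams,
    WeibullParams,
    peleg_equilibrium,
    peleg_moisture,
    proposed_moisture,
    weibull_moisture,
)

__all__ = [
    "RehydrationCurve",
    "FitStats",
    "ModelFit",
    "DegenerateCurveError",
    "fit_peleg",
    "fit_weibull",
    "fit_proposed",
    "fit_all_models",
    "goodness_of_fit",
    "rank_models",
    "predict_moisture",
]

MODEL_NAMES = ("peleg", "weibull", "proposed")

# scipy.optimize.least_squares settings shared by all nonlinear refinements
_LSQ_OPTS = dict(method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=1000)


class DegenerateCurveError(ValueError):
    """Raised when a curve carries no usable rehydration signal (flat, etc.)."""


@dataclass(frozen=True)
class RehydrationCurve:
    """One condition's soaking time series.

    pretreatment  : one of {"control", "HB", "SB", "MB"}.
    temperature_c : drying temperature, °C.
    times         : soaking times, min, strictly increasing, >= 4 points.
    moistures     : dry-basis moisture (g water / g dry matter) at each time.
    Xw0           : initial moisture (the t = 0 moisture), g/g.

    Measured moistures are physically non-negative and validated as such.
    ``allow_negative_moisture=True`` relaxes that check for synthetic
    curves generated from the logarithmic model, whose printed form takes
    negative values at short times for realistic rate parameters.
    """

    pretreatment: str
    temperature_c: float
    times: np.ndarray
    moistures: np.ndarray
    Xw0: float
    allow_negative_moisture: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.moistures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "moistures", x)
        if t.ndim != 1 or x.ndim != 1 or len(t) != len(x):
            raise ValueError("times and moistures must be 1-D and equally long")
        if len(t) < 4:
            raise ValueError(f"a rehydration curve needs >= 4 points, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if not self.allow_negative_moisture and np.any(x < 0):
            raise ValueError("moistures must be >= 0")
        if self.Xw0 < 0:
            raise ValueError("Xw0 must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.pretreatment}_{self.temperature_c:g}C"


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary for one model on one curve."""

    R2: float
    RMSE: float
    chi2: float
    N: int
    Z: int


@dataclass(frozen=True)
class ModelFit:
    """Fitted parameters plus statistics for one model on one curve."""

    model: str
    params: Union[PelegParams, WeibullParams, ProposedParams, None]
    Xeq_derived: Optional[float]
    stats: Optional[FitStats]
    converged: bool
    curve_label: str = field(default="")


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float], Z: int) -> FitStats:
    """RMSE, reduced chi-square and R² for one model's predictions.

    Requires N > Z observations and non-constant observed values
    (otherwise R² is undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equally long")
    n = len(obs)
    if n <= Z:
        raise ValueError(f"need N > Z observations for reduced chi-square (N={n}, Z={Z})")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are constant; R^2 is undefined")
    return FitStats(
        R2=1.0 - sse / sst,
        RMSE=math.sqrt(sse / n),
        chi2=sse / (n - Z),
        N=n,
        Z=Z,
    )


def _stats_values(curve: RehydrationCurve, obs: np.ndarray, pred: np.ndarray,
                  Z: int, residual_on: str) -> FitStats:
    if residual_on == "moisture":
        return goodness_of_fit(obs, pred, Z)
    if residual_on == "moisture_ratio":
        span = obs[-1] - curve.Xw0
        if span == 0.0:
            raise DegenerateCurveError("no net moisture gain; moisture ratio undefined")
        return goodness_of_fit((obs - curve.Xw0) / span, (pred - curve.Xw0) / span, Z)
    raise ValueError(f"unknown residual variable {residual_on!r}")


def fit_peleg(curve: RehydrationCurve, residual_on: str = "moisture") -> ModelFit:
    """Fit the Peleg model by its linearisation followed by nonlinear refinement.

    The linear form t/(X - Xw0) = k1 + k2*t is fitted by ordinary least
    squares over points with X > Xw0 and t > 0, then (k1, k2) are refined
    by trust-region least squares on the moisture residuals of all points.
    """
    t, x = curve.times, curve.moistures
    mask = (t > 0) & (x > curve.Xw0)
    if mask.sum() < 2:
        raise DegenerateCurveError(
            f"curve {curve.label}: fewer than 2 points with moisture above Xw0"
        )
    y = t[mask] / (x[mask] - curve.Xw0)
    k2_0, k1_0 = np.polyfit(t[mask], y, 1)
    x0 = np.array([max(k1_0, 1e-6), max(k2_0, 1e-6)])

    def resid(p):
        return peleg_moisture(t, curve.Xw0, PelegParams(p[0], p[1])) - x

    res = least_squares(resid, x0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), **_LSQ_OPTS)
    converged = bool(res.success)
    params = PelegParams(float(res.x[0]), float(res.x[1]))
    stats = None
    xeq = peleg_equilibrium(curve.Xw0, params.k2)
    if converged:
        stats = _stats_values(curve, x, peleg_moisture(t, curve.Xw0, params), 2, residual_on)
    return ModelFit("peleg", params, xeq, stats, converged, curve.label)


def fit_weibull(curve: RehydrationCurve, residual_on: str = "moisture") -> ModelFit:
    """Fit the Weibull model (alpha, beta, Xeq) with Xw0 fixed.

    Initialisation: alpha = 1, Xeq = 1.05 * max observed moisture, beta =
    the observation time closest to the 63 % level of (Xeq_init - Xw0).
    Bounds: alpha in (0, 5], beta > 0, Xeq >= 0.5 * max observed moisture.
    """
    t, x = curve.times, curve.moistures
    xmax = float(x.max())
    if xmax <= curve.Xw0:
        raise DegenerateCurveError(f"curve {curve.label}: no moisture gain above Xw0")
    xeq0 = xmax * 1.05
    target = curve.Xw0 + (1.0 - math.exp(-1.0)) * (xeq0 - curve.Xw0)
    pos = t[t > 0]
    beta0 = float(pos[np.argmin(np.abs(x[t > 0] - target))]) if len(pos) else 1.0
    x0 = np.array([1.0, beta0, xeq0])
    lo = [1e-9, 1e-9, 0.5 * xmax]
    hi = [5.0, np.inf, np.inf]
    x0 = np.clip(x0, lo, [5.0, 1e12, 1e12])

    def resid(p):
        return weibull_moisture(t, curve.Xw0, WeibullParams(p[0], p[1], max(p[2], 0.0))) - x

    res = least_squares(resid, x0, bounds=(lo, hi), **_LSQ_OPTS)
    converged = bool(res.success)
    params = WeibullParams(float(res.x[0]), float(res.x[1]), float(max(res.x[2], 0.0)))
    stats = None
    if converged:
        stats = _stats_values(curve, x, weibull_moisture(t, curve.Xw0, params), 3, residual_on)
    return ModelFit("weibull", params, params.Xeq, stats, converged, curve.label)


def fit_proposed(curve: RehydrationCurve, residual_on: str = "moisture") -> ModelFit:
    """Fit the logarithmic model via its closed form.

    The model is linear in ln t: X = a + b*ln t with b = Xw0 - Xeq and
    a = Xeq + b*ln k, so ordinary least squares of X on ln t gives
    Xeq = Xw0 - b and k = exp((a - Xeq)/b) exactly.  Points at t = 0 are
    excluded (log singularity).
    """
    mask = curve.times > 0
    t, x = curve.times[mask], curve.moistures[mask]
    if len(t) <= 2:
        raise ValueError(
            f"curve {curve.label}: logarithmic model needs > 2 points with t > 0 (N > Z)"
        )
    b, a = (float(v) for v in np.polyfit(np.log(t), x, 1))
    if abs(b) < 1e-12:
        raise DegenerateCurveError(f"curve {curve.label}: flat regression on ln t")
    xeq = curve.Xw0 - b
    k = math.exp((a - xeq) / b)
    params = ProposedParams(k=k, Xeq=xeq)
    pred = proposed_moisture(t, curve.Xw0, params)
    stats = _stats_values(curve, x, pred, 2, residual_on)
    return ModelFit("proposed", params, xeq, stats, True, curve.label)


def fit_all_models(curve: RehydrationCurve, models: Sequence[str] = MODEL_NAMES,
                   residual_on: str = "moisture") -> list[ModelFit]:
    """Fit every requested model to one curve."""
    dispatch = {"peleg": fit_peleg, "weibull": fit_weibull, "proposed": fit_proposed}
    out = []
    for name in models:
        if name not in dispatch:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        out.append(dispatch[name](curve, residual_on=residual_on))
    return out


def predict_moisture(fit: ModelFit, t, Xw0: float):
    """Evaluate a fitted model at times t."""
    if fit.model == "peleg":
        return peleg_moisture(t, Xw0, fit.params)
    if fit.model == "weibull":
        return weibull_moisture(t, Xw0, fit.params)
    if fit.model == "proposed":
        return proposed_moisture(t, Xw0, fit.params)
    raise ValueError(f"unknown model {fit.model!r}")


def rank_models(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Order converged fits best-first: R² descending, then RMSE, chi² and Z ascending.

    The sort is stable, so fits with identical statistics keep input order.
    """
    usable = [f for f in fits if f.converged and f.stats is not None]
    if not usable:
        raise ValueError("no converged fits to rank")
    return sorted(usable, key=lambda f: (-f.stats.R2, f.stats.RMSE, f.stats.chi2, f.stats.Z))
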