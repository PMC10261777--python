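"""Closed-form rehydration kinetics models for dried kernels.

Three empirical models describe the dry-basis moisture content X(t)
(g water / g dry matter) of a dried kernel soaking in water at time t
(minutes):

* **Peleg** — hyperbolic sorption, ``X(t) = Xw0 + t / (k1 + k2*t)``.
  ``k1`` (min·g dm/g water) is the rate constant: a low k1 means fast
  initial uptake.  ``k2`` (g dm/g water) is the capacity constant: the
  curve saturates at the equilibrium moisture ``Xeq = Xw0 + 1/k2``.
* **Weibull** — stretched-exponential relaxation,
  ``X(t) = Xeq + (Xw0 - Xeq) * exp(-(t/beta)**alpha)``.
  ``alpha`` (–) is the shape factor (uptake sigmoidicity); ``beta``
  (min) is the scale factor, the time at which 1 - 1/e ≈ 63 % of the
  total moisture gain has been attained, for every alpha.
* **Logarithmic** — ``X(t) = Xeq + (Xw0 - Xeq) * ln(k*t)``, linear in
  ln t with slope (Xw0 - Xeq); ``k`` (1/min) sets the time scale.  The
  logarithm is undefined at t = 0, so the model's domain is t > 0.
  Because an increasing curve forces a fitted Xeq below Xw0, the
  "equilibrium" parameter of this model is a fit coefficient that may
  be non-physical; it is reported exactly as fitted, never reinterpreted.

All functions accept scalar or array times and are pure: they are the
forward models consumed by the fitting and synthetic-data layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PelegParams",
    "WeibullParams",
    "ProposedParams",
    "MoistureState",
    "peleg_moisture",
    "peleg_equilibrium",
    "weibull_moisture",
    "proposed_moisture",
]


@dataclass(frozen=True)
class PelegParams:
    """Peleg model parameters.

    k1 : rate constant, min·(g dry matter / g water); k1 > 0.
    k2 : capacity constant, (g dry matter / g water); k2 > 0.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k1) and self.k1 > 0):
            raise ValueError(f"Peleg k1 must be finite and > 0, got {self.k1}")
        if not (math.isfinite(self.k2) and self.k2 > 0):
            raise ValueError(f"Peleg k2 must be finite and > 0, got {self.k2}")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull model parameters.

    alpha : shape factor, dimensionless; alpha > 0.
    beta  : scale factor, min; beta > 0.
    Xeq   : equilibrium moisture, g water / g dry matter; Xeq >= 0.
    """

    alpha: float
    beta: float
    Xeq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"Weibull alpha must be finite and > 0, got {self.alpha}")
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"Weibull beta must be finite and > 0, got {self.beta}")
        if not (math.isfinite(self.Xeq) and self.Xeq >= 0):
            raise ValueError(f"Weibull Xeq must be finite and >= 0, got {self.Xeq}")


@dataclass(frozen=True)
class ProposedParams:
    """Logarithmic model parameters.

    k   : rehydration rate parameter, 1/min; k > 0.
    Xeq : fitted equilibrium-moisture coefficient, g/g.  May be negative
          (below the initial moisture) on increasing curves; see module
          docstring.
    """

    k: float
    Xeq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"logarithmic-model k must be finite and > 0, got {self.k}")
        if not math.isfinite(self.Xeq):
            raise ValueError(f"logarithmic-model Xeq must be finite, got {self.Xeq}")


@dataclass(frozen=True)
class MoistureState:
    """A (time, moisture) point on a rehydration curve, dry basis."""

    Xw0: float
    Xwt: float
    t: float

    def __post_init__(self) -> None:
        if self.Xw0 < 0:
            raise ValueError("initial moisture Xw0 must be >= 0")
        if self.t < 0:
            raise ValueError("soaking time t must be >= 0")


def _as_time(t, allow_zero: bool = True):
    """Validate soaking times; returns (array, was_scalar)."""
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("soaking time must be finite")
    if allow_zero:
        if np.any(arr < 0):
            raise ValueError("soaking time must be >= 0")
    else:
        if np.any(arr <= 0):
            raise ValueError("soaking time must be > 0 (model undefined at t = 0)")
    return arr, arr.ndim == 0


def _ret(values: np.ndarray, scalar: bool):
    return float(values) if scalar else values


def peleg_moisture(t, Xw0: float, params: PelegParams):
    """Peleg moisture at time t: ``Xw0 + t / (k1 + k2*t)``.

    Strictly increasing in t, bounded above by ``Xw0 + 1/k2``.
    """
    arr, scalar = _as_time(t)
    return _ret(Xw0 + arr / (params.k1 + params.k2 * arr), scalar)


def peleg_equilibrium(Xw0: float, k2: float) -> float:
    """Peleg equilibrium moisture, the t → ∞ limit ``Xw0 + 1/k2``."""
    if not (math.isfinite(k2) and k2 > 0):
        raise ValueError(f"Peleg k2 must be finite and > 0, got {k2}")
    return Xw0 + 1.0 / k2


def weibull_moisture(t, Xw0: float, params: WeibullParams):
    """Weibull moisture at time t: ``Xeq + (Xw0 - Xeq) * exp(-(t/beta)**alpha)``."""
    arr, scalar = _as_time(t)
    decay = np.exp(-((arr / params.beta) ** params.alpha))
    # convex-combination form: exact Xw0 at decay=1 and exact Xeq at decay=0
    return _ret(params.Xeq * (1.0 - decay) + Xw0 * decay, scalar)


def proposed_moisture(t, Xw0: float, params: ProposedParams):
    """Logarithmic-model moisture at time t: ``Xeq + (Xw0 - Xeq) * ln(k*t)``.

    Defined for t > 0 only; t <= 0 raises rather than being clipped.
    """
    arr, scalar = _as_time(t, allow_zero=False)
    return _ret(params.Xeq + (Xw0 - params.Xeq) * np.log(params.k * arr), scalar)
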