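"""Physical and colour quality metrics for dried/rehydrated kernels.

Covers the mass-based rehydration ratio, finite-difference rehydration
rates from a soaking curve, the geometric mean diameter of a kernel from
its three mutually normal dimensions, the CIE76 total colour difference
ΔE between two CIELAB triples, and wet-/dry-basis moisture conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import RehydrationCurve

__all__ = [
    "KernelDimensions",
    "ColorLab",
    "MassPair",
    "RehydrationRates",
    "rehydration_ratio",
    "rehydration_rate",
    "geometric_mean_diameter",
    "total_color_difference",
    "moisture_wb_to_db",
    "moisture_db_to_wb",
]


@dataclass(frozen=True)
class KernelDimensions:
    """Kernel length, width and thickness in mm; L is the maximum dimension."""

    L: float
    W: float
    T: float

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.T > 0):
            raise ValueError("kernel dimensions must be > 0")
        if self.L < self.W or self.L < self.T:
            raise ValueError("L must be the maximum dimension (L >= W and L >= T)")


@dataclass(frozen=True)
class ColorLab:
    """A CIELAB colour triple (L*, a*, b*)."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class MassPair:
    """Dried and rehydrated sample masses in grams."""

    mass_dried: float
    mass_rehydrated: float

    def __post_init__(self) -> None:
        if self.mass_dried <= 0 or self.mass_rehydrated <= 0:
            raise ValueError("masses must be > 0")


@dataclass(frozen=True)
class RehydrationRates:
    """Interval (finite-difference) and endpoint-average rehydration rates.

    Units: g water / (g dry matter · min).  ``interval_rates[i]`` is the
    rate over (t_i, t_{i+1}); ``average`` is (X_N - X_0)/(t_N - t_0).
    """

    interval_rates: np.ndarray
    average: float


def rehydration_ratio(pair: MassPair) -> float:
    """Rehydration ratio RR = rehydrated mass / dried mass (dimensionless)."""
    return pair.mass_rehydrated / pair.mass_dried


def rehydration_rate(curve: RehydrationCurve) -> RehydrationRates:
    """Finite-difference and average moisture-gain rates of a soaking curve."""
    t, x = curve.times, curve.moistures
    if len(t) < 2:
        raise ValueError("rehydration rate needs at least two points")
    rates = np.diff(x) / np.diff(t)
    avg = float((x[-1] - x[0]) / (t[-1] - t[0]))
    return RehydrationRates(interval_rates=rates, average=avg)


def geometric_mean_diameter(dims: KernelDimensions) -> float:
    """Geometric mean diameter D_g = (L·W·T)^(1/3), mm."""
    return float((dims.L * dims.W * dims.T) ** (1.0 / 3.0))


def total_color_difference(reference: ColorLab, sample: ColorLab) -> float:
    """CIE76 total colour difference ΔE between two Lab triples.

    Euclidean distance in CIELAB space; symmetric in its arguments.  The
    reference is conventionally the fresh kernel's colour.
    """
    return math.sqrt(
        (reference.L_star - sample.L_star) ** 2
        + (reference.a_star - sample.a_star) ** 2
        + (reference.b_star - sample.b_star) ** 2
    )


def moisture_wb_to_db(wb_fraction: float) -> float:
    """Convert a wet-basis moisture fraction to dry basis (g water / g dry matter)."""
    if not 0.0 <= wb_fraction < 1.0:
        raise ValueError("wet-basis moisture fraction must lie in [0, 1)")
    return wb_fraction / (1.0 - wb_fraction)


def moisture_db_to_wb(db: float) -> float:
    """Convert a dry-basis moisture (g/g) to a wet-basis fraction."""
    if db < 0:
        raise ValueError("dry-basis moisture must be >= 0")
    return db / (1.0 + db)
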