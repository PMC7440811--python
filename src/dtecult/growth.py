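"""Growth curves when only a subpopulation of cells divides.

If a culture starts at density N0 with a fraction ``f`` of cells able to
divide (continuous per-cell rate ``mu`` per day) and the nondividing cells
persist rather than die, the whole-culture density is

    N(t) = N0 * ((1 - f) + f * exp(mu * t))

At late times this is log-linear with slope ``mu``, so a conventional
whole-culture rate fit understates the per-cell rate of the dividing
subpopulation whenever f < 1: the apparent rate over any finite window is
strictly below ``mu``. This is the quantitative face of the dormancy
hypothesis -- a mostly-dormant population can still show clean logarithmic
growth while its active cells divide much faster than the bulk rate
suggests.

An optional carrying capacity applies a smooth logistic-style saturation
N_cap(t) = K * N(t) / (K + N(t) - N0), which preserves N(0) = N0 and early
exponential behaviour while plateauing at K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import ValidationError


@dataclass(frozen=True)
class GrowthParams:
    initial_density: float
    dividing_fraction: float
    per_cell_rate: float
    carrying_capacity: float | None = None

    def __post_init__(self) -> None:
        if not self.initial_density > 0:
            raise ValidationError("initial_density must be positive")
        if not 0.0 <= self.dividing_fraction <= 1.0:
            raise ValidationError("dividing_fraction must be in [0, 1]")
        if self.per_cell_rate < 0:
            raise ValidationError("per_cell_rate must be non-negative")
        if self.carrying_capacity is not None and not (
            self.carrying_capacity >= self.initial_density
        ):
            raise ValidationError("carrying_capacity must be >= initial_density")


@dataclass(frozen=True)
class GrowthCurve:
    times: np.ndarray
    densities: np.ndarray
    params: GrowthParams


def simulate_growth(params: GrowthParams, times) -> GrowthCurve:
    """Deterministic closed-form curve of whole-culture density vs time."""

    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) < 0):
        raise ValidationError("times must be sorted ascending from >= 0")
    f = params.dividing_fraction
    n = params.initial_density * ((1.0 - f) + f * np.exp(params.per_cell_rate * t))
    if params.carrying_capacity is not None:
        k = params.carrying_capacity
        n = k * n / (k + n - params.initial_density)
    return GrowthCurve(times=t, densities=n, params=params)


def apparent_rate(curve: GrowthCurve, window: tuple[float, float]) -> float:
    """Whole-culture growth rate: least-squares slope of ln(N) vs t.

    This is the conventional estimate a reader would take from a growth
    curve assuming every cell divides.
    """

    t0, t1 = window
    mask = (curve.times >= t0) & (curve.times <= t1)
    if mask.sum() < 2:
        raise ValidationError("window must contain at least 2 time points")
    t = curve.times[mask]
    n = curve.densities[mask]
    if np.any(n <= 0):
        raise ValidationError("densities must be positive for a log-linear fit")
    slope, _ = np.polyfit(t, np.log(n), 1)
    return float(slope)


def rate_from_generation_time(generation_time: float) -> float:
    """Continuous rate equivalent of a binary-fission generation time:
    mu = ln(2) / g."""

    if not generation_time > 0:
        raise ValidationError("generation_time must be positive")
    return math.log(2.0) / generation_time
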