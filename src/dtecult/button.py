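"""Closed-form whole-community viability (Button estimator).

For a DTE experiment with ``n`` wells, ``z`` of them positive (p = z/n) and
Poisson inoculum mean ``lam``, the classic most-probable-number style
estimator of whole-community viability is

    V = -ln(1 - p) / lam

The asymptotic standard error propagates the binomial sampling error of p
through the estimator by the delta method:

    ASE = sqrt(p / (n * (1 - p))) / lam

Known pathologies are preserved rather than hidden: the estimator is
undefined at p = 1, and at high p with small ``lam`` it can exceed 1 (100%
viability); such values are returned with ``exceeds_unity`` set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records import ValidationError


@dataclass(frozen=True)
class ButtonEstimate:
    """Viability estimate with delta-method standard error.

    ``viability``, ``ase`` are fractions; ``cv = ase / viability`` when the
    estimate is positive (``nan`` at viability 0, where the relative error
    diverges).
    """

    viability: float
    ase: float
    cv: float
    p: float
    inoculum_lambda: float
    n_wells: int
    positive_wells: int
    exceeds_unity: bool


def button_viability(z: int, n: int, lam: float) -> ButtonEstimate:
    """Estimate whole-community viability from z positive wells of n."""

    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if not lam > 0:
        raise ValidationError(f"lambda must be > 0, got {lam}")
    if z < 0 or z > n:
        raise ValidationError(f"z={z} outside [0, n={n}]")
    if z == n:
        raise ValidationError(
            "equation invalid at p=1 (all wells positive); "
            "use the Monte Carlo viability scan instead"
        )
    p = z / n
    viability = -math.log1p(-p) / lam
    ase = math.sqrt(p / (n * (1.0 - p))) / lam
    cv = ase / viability if viability > 0 else math.nan
    return ButtonEstimate(
        viability=viability,
        ase=ase,
        cv=cv,
        p=p,
        inoculum_lambda=lam,
        n_wells=n,
        positive_wells=z,
        exceeds_unity=viability > 1.0,
    )


def expected_singleton_wells(n: int, lam: float) -> float:
    """Analytic expectation of wells receiving exactly one cell: n*lam*e^-lam.

    The bootstrapped counterpart (median and CI) lives in the simulator.
    """

    if n < 0:
        raise ValidationError(f"n must be non-negative, got {n}")
    if not lam > 0:
        raise ValidationError(f"lambda must be > 0, got {lam}")
    return n * lam * math.exp(-lam)
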