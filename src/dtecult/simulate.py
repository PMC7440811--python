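"""Monte Carlo generative model of a DTE cultivation experiment.

The generative model for one well, given inoculum mean ``lam``, taxon
relative abundance ``r`` and taxon viability ``v``:

1. ``total_cells ~ Poisson(lam)``
2. ``taxon_cells ~ Binomial(total_cells, r)``
3. a well is *positive* if ``taxon_cells >= 1`` and *pure* if it is non-empty
   and every cell belongs to the taxon;
4. for pure wells only, ``viable_cells ~ Binomial(taxon_cells, v)``; a pure
   well is *observed pure* (i.e. yields an isolate) if at least one of its
   cells is viable.

Wells are i.i.d., so each per-well event has a closed-form probability and
the count of wells with that event over ``n`` wells is exactly
``Binomial(n, q)``:

====================  ==========================================
positive              ``1 - exp(-lam * r)``
pure                  ``exp(-lam) * (exp(lam*r) - 1)``
observed pure         ``exp(-lam) * (exp(lam*r) - exp(lam*r*(1-v)))``
singleton (1 cell)    ``lam * exp(-lam)``
====================  ==========================================

``bootstrap_summary`` replays the generative model per bootstrap replicate;
``fast_bootstrap_summary`` draws the replicate counts directly from the
matching binomial and is distributionally identical.

Setting ``r = 1`` recovers the whole-community view: every non-empty well is
pure, and a well is observed positive iff it received at least one viable
cell (per-well probability ``1 - exp(-lam * v)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .records import RunConfig, ValidationError

STATISTICS = ("positive", "pure", "observed_pure", "singleton")


@dataclass(frozen=True)
class WellPlateDesign:
    """Shape of one experiment: well count and Poisson inoculum mean."""

    n_wells: int
    inoculum_lambda: float

    def __post_init__(self) -> None:
        if self.n_wells <= 0:
            raise ValidationError(f"n_wells must be positive, got {self.n_wells}")
        if not self.inoculum_lambda > 0:
            raise ValidationError(
                f"inoculum_lambda must be > 0, got {self.inoculum_lambda}"
            )


class WellCounts(NamedTuple):
    """Tallies from one simulated experiment."""

    positive: int
    pure: int
    observed_pure: int
    singleton: int


@dataclass(frozen=True)
class SimulationSummary:
    """Digest of a bootstrapped count distribution.

    The confidence interval uses empirical order statistics at 1-indexed
    ranks ``ceil(alpha/2 * (B+1))`` and ``floor((1-alpha/2) * (B+1))`` on the
    sorted counts, without interpolation -- the statistic is integer-valued.
    """

    statistic: str
    median: int
    ci_lower: int
    ci_upper: int
    mean: float
    n_bootstraps: int
    seed: int
    fast_path: bool = False

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        statistic: str,
        ci_level: float,
        seed: int,
        fast_path: bool = False,
    ) -> "SimulationSummary":
        counts = np.sort(np.asarray(counts))
        b = counts.size
        alpha = 1.0 - ci_level
        lo_rank = max(math.ceil(alpha / 2.0 * (b + 1)), 1)
        hi_rank = min(math.floor((1.0 - alpha / 2.0) * (b + 1)), b)
        return cls(
            statistic=statistic,
            median=int(np.median(counts)),
            ci_lower=int(counts[lo_rank - 1]),
            ci_upper=int(counts[hi_rank - 1]),
            mean=float(counts.mean()),
            n_bootstraps=b,
            seed=seed,
            fast_path=fast_path,
        )

    def contains(self, observed: int) -> bool:
        return self.ci_lower <= observed <= self.ci_upper


def substream(seed: int, *key: int) -> np.random.Generator:
    """Named RNG substream: results never depend on execution order."""

    parts = [int(seed) & 0x7FFFFFFF, *(int(k) & 0x7FFFFFFF for k in key)]
    return np.random.default_rng(np.random.SeedSequence(parts))


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


def simulate_experiment_once(
    design: WellPlateDesign,
    r: float,
    viability: float,
    rng: np.random.Generator,
) -> WellCounts:
    """Simulate one experiment and tally the four well categories."""

    _check_fraction("r", r)
    _check_fraction("viability", viability)
    total = rng.poisson(design.inoculum_lambda, design.n_wells)
    taxon = rng.binomial(total, r)
    pure_mask = (total >= 1) & (taxon == total)
    viable = rng.binomial(taxon[pure_mask], viability)
    return WellCounts(
        positive=int((taxon >= 1).sum()),
        pure=int(pure_mask.sum()),
        observed_pure=int((viable >= 1).sum()),
        singleton=int((total == 1).sum()),
    )


def analytic_positive_prob(lam: float, r: float) -> float:
    """P(a well holds >= 1 taxon cell): thinned Poisson."""

    _check_fraction("r", r)
    return -math.expm1(-lam * r)


def analytic_pure_prob(lam: float, r: float) -> float:
    """P(a well is non-empty and all its cells belong to the taxon)."""

    _check_fraction("r", r)
    return math.exp(-lam) * math.expm1(lam * r)


def analytic_observed_pure_prob(lam: float, r: float, viability: float) -> float:
    """P(a well is pure with >= 1 viable cell), i.e. yields an isolate."""

    _check_fraction("r", r)
    _check_fraction("viability", viability)
    return math.exp(-lam) * (math.exp(lam * r) - math.exp(lam * r * (1.0 - viability)))


def analytic_singleton_prob(lam: float) -> float:
    """P(a well receives exactly one cell): Poisson pmf at 1."""

    return lam * math.exp(-lam)


def well_probability(
    statistic: str, lam: float, r: float, viability: float
) -> float:
    if statistic == "positive":
        return analytic_positive_prob(lam, r)
    if statistic == "pure":
        return analytic_pure_prob(lam, r)
    if statistic == "observed_pure":
        return analytic_observed_pure_prob(lam, r, viability)
    if statistic == "singleton":
        return analytic_singleton_prob(lam)
    raise ValidationError(f"unknown statistic {statistic!r}; expected {STATISTICS}")


def _check_bootstrap_count(b: int, ci_level: float) -> None:
    if b < 40 and ci_level >= 0.95:
        warnings.warn(
            f"only {b} bootstraps: {ci_level:.0%} CI quantiles are ill-defined",
            stacklevel=3,
        )


def bootstrap_summary(
    design: WellPlateDesign,
    r: float,
    viability: float,
    config: RunConfig,
    statistic: str = "observed_pure",
    n_bootstraps: int | None = None,
    stream_key: tuple[int, ...] = (),
) -> SimulationSummary:
    """Replay the generative model B times and summarise one statistic.

    Each replicate runs on its own RNG substream keyed by
    ``(rng_seed, *stream_key, replicate_index)``.
    """

    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; expected {STATISTICS}")
    b = config.n_bootstraps if n_bootstraps is None else n_bootstraps
    _check_bootstrap_count(b, config.ci_level)
    idx = STATISTICS.index(statistic)
    counts = np.empty(b, dtype=np.int64)
    for rep in range(b):
        rng = substream(config.rng_seed, *stream_key, rep)
        counts[rep] = simulate_experiment_once(design, r, viability, rng)[idx]
    return SimulationSummary.from_counts(
        counts, statistic, config.ci_level, config.rng_seed
    )


def fast_bootstrap_summary(
    design: WellPlateDesign,
    r: float,
    viability: float,
    config: RunConfig,
    statistic: str = "observed_pure",
    n_bootstraps: int | None = None,
    stream_key: tuple[int, ...] = (),
) -> SimulationSummary:
    """Binomial shortcut for the bootstrap: wells are i.i.d., so each
    replicate count is Binomial(n_wells, q) with q the closed-form per-well
    probability. Distributionally identical to :func:`bootstrap_summary`."""

    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; expected {STATISTICS}")
    b = config.n_bootstraps if n_bootstraps is None else n_bootstraps
    _check_bootstrap_count(b, config.ci_level)
    q = well_probability(statistic, design.inoculum_lambda, r, viability)
    rng = substream(config.rng_seed, *stream_key)
    counts = rng.binomial(design.n_wells, q, size=b)
    return SimulationSummary.from_counts(
        counts, statistic, config.ci_level, config.rng_seed, fast_path=True
    )
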