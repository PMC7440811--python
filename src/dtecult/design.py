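"""Power and design utilities for DTE cultivation experiments.

Two design questions recur when planning a campaign:

* How many wells are needed before failing to culture a taxon of abundance
  ``r`` is statistically informative (i.e. a zero is significantly depleted
  rather than merely plausible)?
* Conversely, at a fixed well count, how abundant must a taxon be for a zero
  to mean anything?

Both are answered by the same criterion: the bootstrapped 2.5% quantile of
the observed-pure-well count at V = 100% reaches 1, so that an observation
of zero falls below the 95% CI. Design scans default to 999 bootstraps
(``RunConfig.design_bootstraps``) and step well counts in whole plates of
92 usable wells.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import RunConfig, ValidationError
from .simulate import (
    SimulationSummary,
    WellPlateDesign,
    bootstrap_summary,
    fast_bootstrap_summary,
)

#: Inoculum sizes (cells/well) used in the study's design scans; a preset,
#: not a constraint.
LAMBDA_PRESET = (1.0, 1.27, 1.96, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class DesignQuery:
    """Inputs for a wells-required query."""

    rel_abundance: float
    inoculum_lambda: float
    viability: float = 1.0
    plate_size: int = 92
    max_wells: int = 9200

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_abundance <= 1.0:
            raise ValidationError(
                f"rel_abundance must be in [0,1], got {self.rel_abundance}"
            )
        if not 0.0 <= self.viability <= 1.0:
            raise ValidationError(f"viability must be in [0,1], got {self.viability}")
        if not self.inoculum_lambda > 0:
            raise ValidationError("inoculum_lambda must be > 0")
        if self.plate_size <= 0:
            raise ValidationError("plate_size must be positive")
        if self.max_wells % self.plate_size != 0:
            raise ValidationError(
                f"max_wells={self.max_wells} is not a multiple of "
                f"plate_size={self.plate_size}"
            )


def wells_required(query: DesignQuery, config: RunConfig) -> int | None:
    """Smallest whole-plate well count at which zero recovery is unlikely.

    Scans n = plate_size, 2*plate_size, ..., max_wells and returns the first
    n whose bootstrapped 95% CI lower bound of observed pure wells is >= 1;
    ``None`` when no n up to ``max_wells`` qualifies. All scan points share
    one bootstrap substream (common random numbers), so the pass indicator
    crosses once instead of flickering at the boundary.
    """

    for k in range(1, query.max_wells // query.plate_size + 1):
        n = k * query.plate_size
        summary = fast_bootstrap_summary(
            WellPlateDesign(n, query.inoculum_lambda),
            query.rel_abundance,
            query.viability,
            config,
            "observed_pure",
            n_bootstraps=config.design_bootstraps,
        )
        if summary.ci_lower >= 1:
            return n
    return None


def min_informative_abundance(
    n_wells: int,
    inoculum_lambda: float,
    viability: float,
    config: RunConfig,
) -> float | None:
    """Smallest grid abundance at which zero pure wells is significantly low.

    Scans r on the 0.1% grid and returns the first abundance whose
    bootstrapped 95% CI lower bound of observed pure wells is >= 1; ``None``
    when even r = 100% leaves zero inside the CI (e.g. at viability 0).
    Scan points share one bootstrap substream (common random numbers) for a
    single boundary crossing.
    """

    design = WellPlateDesign(n_wells, inoculum_lambda)
    step = config.viability_grid_step
    n_steps = round(1.0 / step)
    for i in range(1, n_steps + 1):
        r = min(i * step, 1.0)
        summary = fast_bootstrap_summary(
            design,
            r,
            viability,
            config,
            "observed_pure",
            n_bootstraps=config.design_bootstraps,
        )
        if summary.ci_lower >= 1:
            return r
    return None


def predicted_isolates(
    n_wells: int,
    inoculum_lambda: float,
    rel_abundance: float,
    viability: float,
    config: RunConfig,
) -> SimulationSummary:
    """Expected isolates (observed pure wells) for a planned experiment.

    Design-facing wrapper around the generative bootstrap at the full
    ``RunConfig.n_bootstraps``.
    """

    return bootstrap_summary(
        WellPlateDesign(n_wells, inoculum_lambda),
        rel_abundance,
        viability,
        config,
        "observed_pure",
    )
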