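"""Domain records for DTE cultivation experiments.

A dilution-to-extinction (DTE) experiment inoculates ``n_wells`` wells with a
diluted water sample so that each well receives a Poisson-distributed number
of cells with mean ``inoculum_lambda``. The community composition of the
source water is summarised as fractional relative abundances per taxon
(typically averaged ASV abundances), and cultivation outcomes are recorded as
counts of positive wells (whole community) and pure wells (per taxon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One DTE cultivation experiment.

    Parameters
    ----------
    experiment_id:
        Short label, e.g. a site/date code.
    n_wells:
        Number of inoculated wells.
    inoculum_lambda:
        Mean cells delivered per well (Poisson mean), estimated upstream by
        cell counting; always an input here, never fitted.
    positive_wells:
        Observed count of wells reaching detectable growth (optional).
    in_situ_salinity, medium_salinity:
        Carried-through metadata, not used by any model.
    """

    experiment_id: str
    n_wells: int
    inoculum_lambda: float
    positive_wells: int | None = None
    in_situ_salinity: float | None = None
    medium_salinity: float | None = None

    def __post_init__(self) -> None:
        if not self.experiment_id:
            raise ValidationError("experiment_id must be non-empty")
        if self.n_wells <= 0:
            raise ValidationError(
                f"{self.experiment_id}: n_wells must be positive, got {self.n_wells}"
            )
        if not self.inoculum_lambda > 0:
            raise ValidationError(
                f"{self.experiment_id}: inoculum_lambda must be > 0, "
                f"got {self.inoculum_lambda}"
            )
        if self.positive_wells is not None:
            if self.positive_wells < 0 or self.positive_wells > self.n_wells:
                raise ValidationError(
                    f"{self.experiment_id}: positive_wells={self.positive_wells} "
                    f"outside [0, n_wells={self.n_wells}]"
                )


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon observed in one experiment.

    ``rel_abundance`` is a fraction in [0, 1]; percent values are rejected so
    that a 100-fold unit error cannot slip through silently.
    """

    experiment_id: str
    taxon_id: str
    rel_abundance: float
    observed_pure_wells: int

    def __post_init__(self) -> None:
        if not self.experiment_id or not self.taxon_id:
            raise ValidationError("experiment_id and taxon_id must be non-empty")
        if not 0.0 <= self.rel_abundance <= 1.0:
            raise ValidationError(
                f"{self.experiment_id}/{self.taxon_id}: rel_abundance must be a "
                f"fraction in [0, 1], got {self.rel_abundance} "
                "(percent values are not accepted)"
            )
        if self.observed_pure_wells < 0:
            raise ValidationError(
                f"{self.experiment_id}/{self.taxon_id}: observed_pure_wells "
                f"must be non-negative, got {self.observed_pure_wells}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Global run settings.

    Defaults follow the study conditions: 9,999 bootstraps per simulation,
    95% confidence intervals, a 0.1% viability grid, 92 usable wells per
    96-well plate (four corner controls), and 999 bootstraps for the
    experiment-design scans.
    """

    n_bootstraps: int = 9999
    ci_level: float = 0.95
    viability_grid_step: float = 0.001
    plate_size: int = 92
    rng_seed: int = 0
    design_bootstraps: int = 999

    def __post_init__(self) -> None:
        if self.n_bootstraps <= 0 or self.design_bootstraps <= 0:
            raise ValidationError("bootstrap counts must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must be in (0,1), got {self.ci_level}")
        if self.plate_size <= 0:
            raise ValidationError("plate_size must be positive")
        step = self.viability_grid_step
        if not 0.0 < step < 1.0:
            raise ValidationError(f"viability_grid_step must be in (0,1), got {step}")
        n_steps = round(1.0 / step)
        if abs(n_steps * step - 1.0) > 1e-9:
            raise ValidationError(
                f"viability_grid_step={step} does not divide (0,1) into an "
                "integer grid"
            )

    def replace(self, **kwargs) -> "RunConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return RunConfig(**current)
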