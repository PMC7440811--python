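"""Viability inference from cultivation outcomes.

Two questions are answered per (experiment, taxon) pair:

* Is the observed number of pure wells consistent with every cell being
  viable?  ``compare_actual_vs_expected`` simulates the experiment at
  V = 100% and classifies the observation against the bootstrapped 95% CI,
  reporting a deviance score (observed minus simulated median) when it falls
  outside.

* If not, what range of viabilities *is* consistent?
  ``estimate_viability_range`` scans a 0.1% viability grid and returns the
  smallest and largest grid values whose bootstrapped CI contains the
  observation.  Whole-community viability is the same scan at relative
  abundance one, where a well is observed positive iff it received at least
  one viable cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RunConfig, TaxonRecord, ValidationError
from .simulate import (
    SimulationSummary,
    WellPlateDesign,
    bootstrap_summary,
    fast_bootstrap_summary,
)


@dataclass(frozen=True)
class ExpectationComparison:
    """Observed vs simulated pure-well count for one pair at V = 100%."""

    experiment_id: str
    taxon_id: str
    observed: int
    expected_median: int
    ci_lower: int
    ci_upper: int
    classification: str  # within | above | below
    deviance: int

    @classmethod
    def from_summary(
        cls,
        experiment_id: str,
        taxon_id: str,
        observed: int,
        summary: SimulationSummary,
    ) -> "ExpectationComparison":
        if observed > summary.ci_upper:
            classification = "above"
        elif observed < summary.ci_lower:
            classification = "below"
        else:
            classification = "within"
        deviance = observed - summary.median if classification != "within" else 0
        return cls(
            experiment_id=experiment_id,
            taxon_id=taxon_id,
            observed=observed,
            expected_median=summary.median,
            ci_lower=summary.ci_lower,
            ci_upper=summary.ci_upper,
            classification=classification,
            deviance=deviance,
        )


@dataclass(frozen=True)
class ViabilityRange:
    """Grid viabilities compatible with an observation at the 95% CI.

    ``at_grid_floor`` marks ranges whose minimum is the grid's first point
    (reported like "0.1-..."): the data cannot distinguish viabilities below
    the grid floor. ``inconsistent`` marks observations (typically
    over-cultivated taxa) that no grid viability explains.
    """

    v_min: float
    v_max: float
    grid_step: float
    at_grid_floor: bool
    at_grid_ceiling: bool
    inconsistent: bool


def viability_grid(step: float) -> np.ndarray:
    """The scan grid: step, 2*step, ..., 1 - step (0.1% ... 99.9%)."""

    n = round(1.0 / step)
    return np.arange(1, n) * step


def compare_actual_vs_expected(
    design: WellPlateDesign,
    taxon: TaxonRecord,
    config: RunConfig,
    method: str = "generative",
    stream_key: tuple[int, ...] = (),
) -> ExpectationComparison:
    """Classify one taxon's pure-well count against the V = 100% model."""

    if taxon.rel_abundance == 0 and taxon.observed_pure_wells > 0:
        raise ValidationError(
            f"{taxon.experiment_id}/{taxon.taxon_id}: observed pure wells for a "
            "taxon with zero relative abundance"
        )
    if taxon.observed_pure_wells > design.n_wells:
        raise ValidationError(
            f"{taxon.experiment_id}/{taxon.taxon_id}: observed_pure_wells "
            f"exceeds n_wells={design.n_wells}"
        )
    boot = bootstrap_summary if method == "generative" else fast_bootstrap_summary
    summary = boot(
        design, taxon.rel_abundance, 1.0, config, "observed_pure",
        stream_key=stream_key,
    )
    return ExpectationComparison.from_summary(
        taxon.experiment_id, taxon.taxon_id, taxon.observed_pure_wells, summary
    )


def _scan_range(
    design: WellPlateDesign,
    r: float,
    observed: int,
    config: RunConfig,
    common_random_numbers: bool = False,
) -> ViabilityRange:
    grid = viability_grid(config.viability_grid_step)
    ok = np.zeros(grid.size, dtype=bool)
    for i, v in enumerate(grid):
        key = () if common_random_numbers else (i,)
        summary = fast_bootstrap_summary(
            design, r, float(v), config, "observed_pure", stream_key=key
        )
        ok[i] = summary.contains(observed)
    if not ok.any():
        return ViabilityRange(
            v_min=float("nan"),
            v_max=float("nan"),
            grid_step=config.viability_grid_step,
            at_grid_floor=False,
            at_grid_ceiling=False,
            inconsistent=True,
        )
    hits = np.flatnonzero(ok)
    return ViabilityRange(
        v_min=float(grid[hits[0]]),
        v_max=float(grid[hits[-1]]),
        grid_step=config.viability_grid_step,
        at_grid_floor=bool(hits[0] == 0),
        at_grid_ceiling=bool(hits[-1] == grid.size - 1),
        inconsistent=False,
    )


def estimate_viability_range(
    design: WellPlateDesign,
    taxon: TaxonRecord,
    config: RunConfig,
    common_random_numbers: bool = False,
) -> ViabilityRange:
    """Scan the viability grid for values consistent with the observation.

    Each grid point gets its own bootstrap substream keyed by its index, so
    re-running any single point reproduces the scan's verdict for it; pass
    ``common_random_numbers=True`` to share one substream across the grid,
    which makes counts monotone in V and stabilises the boundary points.
    """

    if taxon.rel_abundance <= 0:
        raise ValidationError(
            f"{taxon.experiment_id}/{taxon.taxon_id}: viability is undefined "
            "for a taxon of zero relative abundance"
        )
    return _scan_range(
        design,
        taxon.rel_abundance,
        taxon.observed_pure_wells,
        config,
        common_random_numbers,
    )


def whole_community_viability_range(
    design: WellPlateDesign,
    z: int,
    config: RunConfig,
    common_random_numbers: bool = False,
) -> ViabilityRange:
    """Whole-community viability range from z observed positive wells.

    The same grid scan at relative abundance one: with r = 1 every non-empty
    well is pure, and a well is observed positive iff at least one of its
    cells is viable (per-well probability 1 - exp(-lambda * V)).
    """

    if z < 0 or z > design.n_wells:
        raise ValidationError(f"z={z} outside [0, n_wells={design.n_wells}]")
    return _scan_range(design, 1.0, z, config, common_random_numbers)


@dataclass(frozen=True)
class CampaignSummary:
    """Tallies over all (experiment, taxon) comparisons of a campaign."""

    n_pairs: int
    n_within: int
    n_above: int
    n_below: int
    deviances: tuple[int, ...]

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n_pairs if self.n_pairs else float("nan")


def campaign_report(
    experiments,
    taxa,
    config: RunConfig,
    method: str = "fast",
) -> tuple[list[ExpectationComparison], CampaignSummary]:
    """Compare every (experiment, taxon) pair against the V = 100% model.

    Output is sorted by (experiment_id, taxon_id). The fast binomial path is
    the default; pass ``method="generative"`` to replay the full well-level
    model per pair.
    """

    designs = {
        e.experiment_id: WellPlateDesign(e.n_wells, e.inoculum_lambda)
        for e in experiments
    }
    orphans = sorted(
        {t.experiment_id for t in taxa if t.experiment_id not in designs}
    )
    if orphans:
        raise ValidationError(
            f"taxa reference unknown experiments: {', '.join(orphans)}"
        )
    seen: set[tuple[str, str]] = set()
    for t in taxa:
        key = (t.experiment_id, t.taxon_id)
        if key in seen:
            raise ValidationError(f"duplicate (experiment, taxon) pair: {key}")
        seen.add(key)
    ordered = sorted(taxa, key=lambda t: (t.experiment_id, t.taxon_id))
    comparisons = [
        compare_actual_vs_expected(
            designs[t.experiment_id], t, config, method, stream_key=(i,)
        )
        for i, t in enumerate(ordered)
    ]
    summary = CampaignSummary(
        n_pairs=len(comparisons),
        n_within=sum(c.classification == "within" for c in comparisons),
        n_above=sum(c.classification == "above" for c in comparisons),
        n_below=sum(c.classification == "below" for c in comparisons),
        deviances=tuple(c.deviance for c in comparisons if c.deviance != 0),
    )
    return comparisons, summary
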