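"""Synthetic cultivation campaigns with known ground-truth viability.

Real DTE campaigns pair an amplicon-derived abundance table with observed
cultivation outcomes; the true per-taxon viability is unknown. This module
builds the same three tables from a fully specified generative process so
that estimators can be tested against known truth:

* mock communities are symmetric-Dirichlet draws (low concentration gives
  the skewed rank-abundance shape typical of coastal bacterioplankton: a few
  taxa above 5%, a long rare tail);
* each taxon's observed pure-well count is forward-simulated through the
  well-level generative model at its assigned true viability;
* each experiment's whole-community positive-well count is drawn from
  Binomial(n, 1 - exp(-lambda * Vbar)) with Vbar the abundance-weighted mean
  viability (taxa are simulated one at a time, so the community positives
  use this single-draw approximation).

Defaults mirror the study design: 17 experiments of 460 wells with inoculum
means drawn from {1.27, 1.5, 1.56, 1.8, 1.96, 2} cells per well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .records import ExperimentRecord, TaxonRecord, ValidationError
from .simulate import WellPlateDesign, simulate_experiment_once, substream

#: Inoculum means (cells/well) used across the 17-experiment study design.
LAMBDA_CHOICES = (1.27, 1.5, 1.56, 1.8, 1.96, 2.0)

#: A taxon's true viability given (rng, taxon_index, abundance).
ViabilityRule = Callable[[np.random.Generator, int, float], float]


def all_viable(rng: np.random.Generator, i: int, r: float) -> float:
    """Every cell of every taxon can grow (V = 1)."""

    return 1.0


def dormant_mixture(
    fraction_dormant: float = 0.2, dormant_viability: float = 0.15
) -> ViabilityRule:
    """A fraction of taxa is mostly dormant (low V), the rest fully viable."""

    def rule(rng: np.random.Generator, i: int, r: float) -> float:
        return (
            dormant_viability
            if rng.random() < fraction_dormant
            else 1.0
        )

    return rule


@dataclass(frozen=True)
class MockCampaign:
    experiments: list[ExperimentRecord]
    taxa: list[TaxonRecord]
    truth: dict[tuple[str, str], float]
    seed: int


def generate_mock_community(
    n_taxa: int, concentration: float = 0.1, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Relative abundance vector from a symmetric Dirichlet(concentration)."""

    if n_taxa < 1:
        raise ValidationError(f"n_taxa must be >= 1, got {n_taxa}")
    if not concentration > 0:
        raise ValidationError(f"concentration must be > 0, got {concentration}")
    if rng is None:
        rng = substream(0 if seed is None else seed)
    abundances = rng.dirichlet(np.full(n_taxa, concentration))
    abundances /= abundances.sum()
    # sorted descending: rank-abundance convention
    return np.sort(abundances)[::-1]


def generate_campaign(
    n_experiments: int = 17,
    wells_per_experiment: int = 460,
    n_taxa: int = 100,
    concentration: float = 0.1,
    lambda_choices: Sequence[float] = LAMBDA_CHOICES,
    viability_rule: ViabilityRule = all_viable,
    seed: int = 0,
) -> MockCampaign:
    """Forward-simulate a whole cultivation campaign.

    Per experiment: draw a community, assign each taxon a true viability by
    ``viability_rule``, then simulate its observed pure wells through the
    well-level generative model. Fully reproducible from ``seed``.
    """

    if n_experiments < 1 or wells_per_experiment < 1:
        raise ValidationError("n_experiments and wells_per_experiment must be >= 1")
    experiments: list[ExperimentRecord] = []
    taxa: list[TaxonRecord] = []
    truth: dict[tuple[str, str], float] = {}
    for e in range(n_experiments):
        rng = substream(seed, e)
        lam = float(rng.choice(np.asarray(lambda_choices)))
        design = WellPlateDesign(wells_per_experiment, lam)
        exp_id = f"EXP{e + 1:02d}"
        abundances = generate_mock_community(n_taxa, concentration, rng=rng)
        vbar = 0.0
        for i, r in enumerate(abundances):
            v = float(viability_rule(rng, i, float(r)))
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"viability rule returned {v}, not in [0,1]")
            taxon_id = f"T{i + 1:04d}"
            counts = simulate_experiment_once(design, float(r), v, rng)
            taxa.append(
                TaxonRecord(
                    experiment_id=exp_id,
                    taxon_id=taxon_id,
                    rel_abundance=float(r),
                    observed_pure_wells=counts.observed_pure,
                )
            )
            truth[(exp_id, taxon_id)] = v
            vbar += float(r) * v
        p_positive = -math.expm1(-lam * vbar)
        z = int(rng.binomial(wells_per_experiment, p_positive))
        experiments.append(
            ExperimentRecord(
                experiment_id=exp_id,
                n_wells=wells_per_experiment,
                inoculum_lambda=lam,
                positive_wells=z,
            )
        )
    return MockCampaign(experiments=experiments, taxa=taxa, truth=truth, seed=seed)


def write_campaign(campaign: MockCampaign, out_dir: str | Path) -> dict[str, Path]:
    """Write experiments.tsv, taxa.tsv and truth.tsv under ``out_dir``."""

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "experiments": out / "experiments.tsv",
        "taxa": out / "taxa.tsv",
        "truth": out / "truth.tsv",
    }
    io.write_records(campaign.experiments, paths["experiments"])
    io.write_records(campaign.taxa, paths["taxa"])
    truth_rows = [
        {"experiment_id": e, "taxon_id": t, "true_viability": v}
        for (e, t), v in sorted(campaign.truth.items())
    ]
    io.write_table(truth_rows, paths["truth"])
    return paths
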