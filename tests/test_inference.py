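import pytest
from scipy import stats

from dtecult import (
    RunConfig,
    TaxonRecord,
    ValidationError,
    WellPlateDesign,
    analytic_observed_pure_prob,
    campaign_report,
    compare_actual_vs_expected,
    estimate_viability_range,
    viability_grid,
    whole_community_viability_range,
)
from dtecult.inference import ExpectationComparison
from dtecult.simulate import SimulationSummary


def summary(median, lo, hi):
    return SimulationSummary("observed_pure", median, lo, hi, float(median), 9999, 0)


class TestClassification:
    def test_within_is_inclusive_of_both_bounds(self):
        for obs, expected in [(13, "within"), (30, "within"), (12, "below"),
                              (31, "above"), (21, "within")]:
            c = ExpectationComparison.from_summary("E", "T", obs, summary(21, 13, 30))
            assert c.classification == expected

    def test_deviance_reported_only_outside_ci(self):
        below = ExpectationComparison.from_summary("E", "T", 0, summary(21, 13, 30))
        assert below.deviance == -21
        above = ExpectationComparison.from_summary("E", "T", 33, summary(21, 13, 30))
        assert above.deviance == 12
        within = ExpectationComparison.from_summary("E", "T", 21, summary(21, 13, 30))
        assert within.deviance == 0


def test_abundant_uncultured_taxon_flagged_below(cfg):
    """A taxon at 14.5% abundance with zero pure wells is far below the
    V=100% expectation of ~21 isolates."""

    c = compare_actual_vs_expected(
        WellPlateDesign(460, 2.0), TaxonRecord("ARD2c", "7629", 0.145, 0), cfg
    )
    assert c.classification == "below"
    assert c.expected_median == 21
    assert c.deviance == -21


def test_rare_taxon_single_isolate_is_within(cfg):
    """At r=0.0005 the 95% CI spans 0..>=1 pure wells, so one isolate is
    unremarkable (analytic binomial quantiles confirm)."""

    q = analytic_observed_pure_prob(2.0, 0.0005, 1.0)
    assert stats.binom.ppf(0.025, 460, q) <= 1 <= stats.binom.ppf(0.975, 460, q)
    c = compare_actual_vs_expected(
        WellPlateDesign(460, 2.0), TaxonRecord("E", "T", 0.0005, 1), cfg,
        method="fast",
    )
    assert c.classification == "within"


def test_absent_taxon_with_isolates_is_contradictory(cfg):
    with pytest.raises(ValidationError):
        compare_actual_vs_expected(
            WellPlateDesign(460, 2.0), TaxonRecord("E", "T", 0.0, 1), cfg
        )


class TestViabilityScan:
    def test_grid_covers_open_unit_interval(self):
        grid = viability_grid(0.001)
        assert grid[0] == pytest.approx(0.001)
        assert grid[-1] == pytest.approx(0.999)
        assert len(grid) == 999

    def test_zero_observed_abundant_taxon_bounds_viability(self, cfg):
        """LD12-like case: zero isolates at ~15% abundance caps viability
        near 15%, with the floor unresolved."""

        vr = estimate_viability_range(
            WellPlateDesign(460, 2.0), TaxonRecord("ARD2c", "7629", 0.15, 0), cfg,
            common_random_numbers=True,
        )
        assert vr.at_grid_floor
        assert not vr.at_grid_ceiling
        assert vr.v_max == pytest.approx(0.15, abs=0.005)

    def test_range_consistency(self, cfg):
        """Every grid point inside the reported range explains the
        observation; points far outside do not (exact binomial check)."""

        design = WellPlateDesign(460, 2.0)
        vr = estimate_viability_range(
            design, TaxonRecord("LKB2", "7629", 0.08, 1), cfg
        )
        for v in (vr.v_min, (vr.v_min + vr.v_max) / 2, vr.v_max):
            q = analytic_observed_pure_prob(2.0, 0.08, v)
            assert stats.binom.cdf(1, 460, q) > 0.01  # 1 not implausibly high
        q_out = analytic_observed_pure_prob(2.0, 0.08, min(vr.v_max + 0.05, 0.999))
        assert stats.binom.cdf(1, 460, q_out) < 0.025

    def test_observed_median_at_full_viability_reaches_ceiling(self, cfg):
        """If the observation equals the V=1 median, the scan includes the
        grid ceiling — and agrees with the actual-vs-expected verdict."""

        design = WellPlateDesign(460, 2.0)
        taxon = TaxonRecord("E", "T", 0.145, 21)
        vr = estimate_viability_range(design, taxon, cfg)
        assert vr.at_grid_ceiling
        c = compare_actual_vs_expected(design, taxon, cfg, method="fast")
        assert c.classification == "within"

    def test_overcultivated_taxon_is_inconsistent(self, cfg):
        """More isolates than any viability can explain -> no range."""

        vr = estimate_viability_range(
            WellPlateDesign(460, 2.0), TaxonRecord("E", "T", 0.001, 60), cfg
        )
        assert vr.inconsistent

    def test_vmax_monotone_in_observed_count(self, cfg):
        """Fewer observed isolates can only lower the compatible viability
        ceiling (common random numbers)."""

        design = WellPlateDesign(460, 2.0)
        vmaxes = []
        for obs in (6, 3, 0):
            vr = estimate_viability_range(
                design, TaxonRecord("E", "T", 0.08, obs), cfg,
                common_random_numbers=True,
            )
            vmaxes.append(vr.v_max)
        assert vmaxes == sorted(vmaxes, reverse=True)

    def test_zero_abundance_rejected(self, cfg):
        with pytest.raises(ValidationError):
            estimate_viability_range(
                WellPlateDesign(460, 2.0), TaxonRecord("E", "T", 0.0, 0), cfg
            )


class TestWholeCommunity:
    def test_nearly_all_positive_experiment(self, cfg):
        """FWC2-like outcome (403/460 positive, lam=2): viability at least
        ~92%, unbounded above — where the closed-form estimator overshoots
        past 100%."""

        vr = whole_community_viability_range(WellPlateDesign(460, 2.0), 403, cfg)
        assert vr.v_min == pytest.approx(0.925, abs=0.003)
        assert vr.at_grid_ceiling

    def test_no_positive_wells_leaves_floor_unresolved(self, cfg):
        vr = whole_community_viability_range(WellPlateDesign(460, 2.0), 0, cfg)
        assert vr.at_grid_floor

    def test_z_out_of_range_rejected(self, cfg):
        with pytest.raises(ValidationError):
            whole_community_viability_range(WellPlateDesign(460, 2.0), 461, cfg)


class TestCampaignReport:
    def make_inputs(self):
        from dtecult import ExperimentRecord

        experiments = [
            ExperimentRecord("E1", 460, 2.0),
            ExperimentRecord("E2", 460, 1.27),
        ]
        taxa = [
            TaxonRecord("E1", "T1", 0.145, 0),
            TaxonRecord("E1", "T2", 0.001, 0),
            TaxonRecord("E2", "T1", 0.05, 3),
        ]
        return experiments, taxa

    def test_report_sorted_and_tallied(self, quick_cfg):
        experiments, taxa = self.make_inputs()
        comparisons, summary = campaign_report(experiments, taxa, quick_cfg)
        assert [(c.experiment_id, c.taxon_id) for c in comparisons] == [
            ("E1", "T1"), ("E1", "T2"), ("E2", "T1")
        ]
        assert summary.n_pairs == 3
        assert summary.n_within + summary.n_above + summary.n_below == 3

    def test_singleton_campaign(self, quick_cfg):
        from dtecult import ExperimentRecord

        comparisons, summary = campaign_report(
            [ExperimentRecord("E1", 460, 2.0)],
            [TaxonRecord("E1", "T1", 0.145, 21)],
            quick_cfg,
        )
        assert summary.n_pairs == 1
        assert comparisons[0].classification == "within"

    def test_orphan_taxon_rejected(self, quick_cfg):
        experiments, taxa = self.make_inputs()
        taxa.append(TaxonRecord("E9", "T1", 0.1, 0))
        with pytest.raises(ValidationError, match="E9"):
            campaign_report(experiments, taxa, quick_cfg)

    def test_duplicate_pair_rejected(self, quick_cfg):
        experiments, taxa = self.make_inputs()
        taxa.append(TaxonRecord("E1", "T1", 0.145, 0))
        with pytest.raises(ValidationError, match="duplicate"):
            campaign_report(experiments, taxa, quick_cfg)
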