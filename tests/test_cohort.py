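"""Paired cohort runs, savings fractions and replicate summaries."""

import numpy as np
import pytest

from oxytitrate import (
    CohortDistributions,
    ScenarioSpec,
    TitrationPolicy,
    liters_to_hours_at_flow,
    run_cohort,
    run_replicates,
    savings_fraction,
)


def degenerate_dists(v0=1.0, d=2, k=0.125):
    """Single-point supports: every sampled patient is identical."""
    return CohortDistributions(
        v0_support=(v0,), v0_probs=(1.0,),
        duration_support=(d,), duration_probs=(1.0,),
        profile_probs=(0.5, 0.5), k=k,
    )


class TestRunCohort:
    def test_single_forced_patient_total(self):
        result = run_cohort(
            degenerate_dists(v0=1.0, d=2), 1,
            [ScenarioSpec("ref", TitrationPolicy.initial_only())], seed=0,
        )
        assert result.totals["ref"] == 2880.0

    def test_scenario_totals_ordered_by_titration_frequency(self, dists, scenarios):
        result = run_cohort(dists, 100, scenarios, seed=3)
        assert result.totals["III"] <= result.totals["II"] <= result.totals["I"]

    def test_totals_equal_sum_of_records(self, dists, scenarios):
        result = run_cohort(dists, 50, scenarios, seed=5)
        for label, records in result.records.items():
            assert result.totals[label] == pytest.approx(
                sum(r.volume for r in records), rel=1e-6
            )
            assert result.cumulative[label][-1] == pytest.approx(result.totals[label])

    def test_paired_design_shares_patients(self, dists, scenarios):
        result = run_cohort(dists, 20, scenarios, seed=9)
        ids = [p.id for p in result.patients]
        for records in result.records.values():
            assert [r.patient_id for r in records] == ids

    def test_deterministic_given_seed(self, dists, scenarios):
        a = run_cohort(dists, 30, scenarios, seed=11)
        b = run_cohort(dists, 30, scenarios, seed=11)
        assert a.patients == b.patients
        assert a.totals == b.totals
        for label in a.cumulative:
            np.testing.assert_array_equal(a.cumulative[label], b.cumulative[label])

    def test_rejects_empty_or_duplicate_scenarios(self, dists):
        with pytest.raises(ValueError):
            run_cohort(dists, 10, [], seed=0)
        spec = ScenarioSpec("x", TitrationPolicy.initial_only())
        with pytest.raises(ValueError):
            run_cohort(dists, 10, [spec, spec], seed=0)


class TestSavingsFraction:
    def test_reference_consistency_with_reported_totals(self):
        # printed cohort totals: 374 kL reference, 344 kL at 24 h, 330 kL at 3 min
        assert savings_fraction(374_000, 344_000) == pytest.approx(0.0802, abs=5e-4)
        assert savings_fraction(374_000, 330_000) == pytest.approx(0.1176, abs=5e-4)

    def test_no_benefit_is_zero(self):
        assert savings_fraction(100.0, 100.0) == 0.0

    def test_rejects_policy_exceeding_reference(self):
        with pytest.raises(ValueError):
            savings_fraction(100.0, 101.0)
        with pytest.raises(ValueError):
            savings_fraction(0.0, 0.0)


class TestRunReplicates:
    def test_requires_at_least_two_replicates(self, dists, scenarios):
        with pytest.raises(ValueError):
            run_replicates(dists, 10, scenarios, 1, base_seed=0)

    def test_no_weaning_nullifies_savings(self, scenarios):
        summary = run_replicates(degenerate_dists(k=0.0), 50, scenarios, 3, base_seed=2)
        for label in ("II", "III"):
            assert summary.mean_savings[label] == 0.0
            assert summary.sem_savings[label] == 0.0

    def test_sem_matches_manual_computation(self, dists, scenarios):
        summary = run_replicates(dists, 100, scenarios, 3, base_seed=4)
        table = summary.replicate_totals
        totals_I = table[table.scenario_label == "I"]["total_liters"].to_numpy()
        assert summary.sem_total["I"] == pytest.approx(
            totals_I.std(ddof=1) / np.sqrt(3)
        )
        assert summary.mean_total["I"] == pytest.approx(totals_I.mean())

    def test_replicates_use_consecutive_seeds(self, dists, scenarios):
        summary = run_replicates(dists, 10, scenarios, 3, base_seed=100)
        assert sorted(summary.replicate_totals["seed"].unique()) == [100, 101, 102]

    def test_savings_in_sanity_band(self, dists, scenarios):
        summary = run_replicates(dists, 100, scenarios, 3, base_seed=8)
        for label in ("II", "III"):
            assert 0.0 < summary.mean_savings[label] < 0.3

    def test_totals_scale_linearly_in_n(self, dists, scenarios):
        small = run_replicates(dists, 100, scenarios, 20, base_seed=50)
        large = run_replicates(dists, 200, scenarios, 20, base_seed=250)
        ratio = large.mean_total["I"] / small.mean_total["I"]
        # CLT: relative SD of each mean is ~0.8-1.2%, so the ratio sits near 2
        assert ratio == pytest.approx(2.0, rel=0.06)


class TestConversions:
    def test_hours_at_one_liter_per_minute(self):
        assert liters_to_hours_at_flow(30_000, 1.0) == pytest.approx(500.0)
        assert liters_to_hours_at_flow(44_000, 1.0) == pytest.approx(733.3, abs=0.05)
        assert liters_to_hours_at_flow(0.0, 1.0) == 0.0

    def test_rejects_non_positive_flow(self):
        with pytest.raises(ValueError):
            liters_to_hours_at_flow(100.0, 0.0)
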