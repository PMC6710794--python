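"""Synthetic patients and registry: determinism, distributional fidelity, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from preecon.costing import InpatientGroup
from preecon.parameters import ConfigurationError, ParameterError, STRATUM_LABELS, load_config
from preecon.synthetic_cohort import (
    RECORD_COLUMNS,
    expected_cost_per_patient,
    recover_parameters,
    simulate_patients,
    simulate_registry,
    summarize,
)


@pytest.fixture(scope="module")
def test_arm_50k(base_config_module):
    return simulate_patients(base_config_module, "test", 50_000, seed=11)


@pytest.fixture(scope="module")
def base_config_module():
    from preecon.parameters import base_case_path

    return load_config(base_case_path())


def binomial_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestSimulatePatients:
    def test_identical_seed_identical_records(self, base_config_module):
        a = simulate_patients(base_config_module, "test", 2000, seed=42)
        b = simulate_patients(base_config_module, "test", 2000, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_single_patient_has_valid_branch(self, base_config_module):
        frame = simulate_patients(base_config_module, "test", 1, seed=0)
        assert list(frame.columns) == list(RECORD_COLUMNS)
        assert frame.loc[0, "branch_id"] in base_config_module.strategies["test"]

    def test_stratum_prevalences_recovered(self, test_arm_50k, base_config_module):
        n = len(test_arm_50k)
        for stratum in base_config_module.strata:
            observed = (test_arm_50k["stratum"] == stratum.label).mean()
            assert abs(observed - stratum.prevalence) <= 3 * binomial_se(stratum.prevalence, n)

    def test_no_test_admission_rate(self, base_config_module):
        frame = simulate_patients(base_config_module, "no_test", 50_000, seed=1)
        rate = base_config_module.cascades["no_test"].p_hospitalized
        observed = frame["initially_hospitalized"].mean()
        assert abs(observed - rate) <= 3 * binomial_se(rate, len(frame))
        assert frame["stratum"].isna().all()

    def test_severe_bp_only_in_ruled_out_stratum_and_admitted(self, test_arm_50k):
        severe = test_arm_50k[test_arm_50k["severe_bp"]]
        assert (severe["stratum"] == "ratio_le_38").all()
        assert severe["initially_hospitalized"].all()

    def test_pathway_cost_is_branch_cost_plus_initial_consultation(
        self, test_arm_50k, base_config_module
    ):
        branches = base_config_module.strategies["test"]
        initial = float(branches["initial_consultation"].per_patient_cost)
        for branch_id in ("low", "suspected_pe_birth"):
            rows = test_arm_50k[test_arm_50k["branch_id"] == branch_id]
            expected = float(branches[branch_id].per_patient_cost) + initial
            assert np.allclose(rows["pathway_cost"].to_numpy(), expected)

    def test_branch_consistency_with_dispositions(self, test_arm_50k):
        admitted = test_arm_50k["initially_hospitalized"]
        pe = test_arm_50k["developed_pe"]
        assert (test_arm_50k.loc[admitted & pe, "branch_id"] == "suspected_pe_birth").all()
        assert (
            test_arm_50k.loc[admitted & ~pe, "branch_id"] == "intermediate_after_hosp"
        ).all()
        assert (test_arm_50k.loc[~admitted & pe, "branch_id"] == "pe_after_ambulatory").all()
        assert set(test_arm_50k.loc[~admitted & ~pe, "branch_id"]) <= {"low", "intermediate"}

    def test_rejects_bad_arguments(self, base_config_module):
        with pytest.raises(ParameterError):
            simulate_patients(base_config_module, "test", 0, seed=1)
        with pytest.raises(ParameterError):
            simulate_patients(base_config_module, "placebo", 10, seed=1)

    def test_counts_only_config_demands_probability_parameters(self, base_config_module):
        from preecon.parameters import serialize_config

        doc = serialize_config(base_config_module)
        del doc["cascades"]
        config = load_config(doc)
        with pytest.raises(ConfigurationError, match="probability"):
            simulate_patients(config, "test", 10, seed=1)


class TestSummarize:
    def test_matches_law_of_large_numbers(self, test_arm_50k, base_config_module):
        summary = summarize(test_arm_50k, base_config_module.cohort_size)
        expected = expected_cost_per_patient(base_config_module, "test")
        assert abs(summary.mean_cost_per_patient - expected) <= 3 * summary.se_mean

    def test_single_record_flags_undefined_se(self, base_config_module):
        frame = simulate_patients(base_config_module, "test", 1, seed=3)
        summary = summarize(frame, 6084)
        assert summary.mean_cost_per_patient == pytest.approx(frame.loc[0, "pathway_cost"])
        assert math.isnan(summary.se_mean)

    def test_identical_costs_have_zero_se(self, base_config_module):
        frame = simulate_patients(base_config_module, "test", 100, seed=3).copy()
        frame["pathway_cost"] = 1234.5
        assert summarize(frame, 6084).se_mean == 0.0

    def test_empty_input_rejected(self, base_config_module):
        frame = simulate_patients(base_config_module, "test", 5, seed=3)
        with pytest.raises(ParameterError):
            summarize(frame.iloc[0:0], 6084)


class TestRegistry:
    def test_deterministic(self, inpatient_groups):
        a = simulate_registry(inpatient_groups, 10, seed=7)
        b = simulate_registry(inpatient_groups, 10, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_group_shares_match_registry_sizes(self, inpatient_groups):
        frame = simulate_registry(inpatient_groups, 50_000, seed=3)
        total = sum(g.n for g in inpatient_groups)
        for group in inpatient_groups:
            share = group.n / total
            observed = (frame["group"] == group.label).mean()
            assert abs(observed - share) <= 3 * binomial_se(share, len(frame))

    def test_moments_converge_to_group_values(self, inpatient_groups):
        frame = simulate_registry(inpatient_groups, 100_000, seed=3)
        for group in inpatient_groups:
            sample = frame.loc[frame["group"] == group.label, "cost"]
            assert sample.mean() == pytest.approx(float(group.cost_mean), rel=0.02)
            assert sample.median() == pytest.approx(float(group.cost_median), rel=0.03)

    def test_positive_and_right_skewed(self, inpatient_groups):
        frame = simulate_registry(inpatient_groups, 20_000, seed=5)
        assert (frame["cost"] > 0).all()
        assert (frame["los_days"] > 0).all()
        grouped = frame.groupby("group")["cost"]
        assert (grouped.mean() > grouped.median()).all()

    def test_mean_below_median_rejected(self):
        from decimal import Decimal

        bad = InpatientGroup("bad", 10, 5.0, 4.0, Decimal(100), Decimal(90))
        with pytest.raises(ConfigurationError):
            simulate_registry([bad], 10, seed=1)


class TestRecoverParameters:
    def test_estimates_track_generating_values(self, test_arm_50k, base_config_module):
        # single-draw sanity bound: each estimate within 3 binomial SE of truth
        # (nominal 95%-CI coverage is checked across replicates below)
        estimates = recover_parameters(test_arm_50k)
        for stratum in base_config_module.strata:
            prev = estimates[f"prevalence_{stratum.label}"]
            assert abs(prev.estimate - stratum.prevalence) <= 3 * binomial_se(
                stratum.prevalence, prev.n_obs
            )
            hosp = estimates[f"p_hospitalized_{stratum.label}"]
            assert abs(hosp.estimate - stratum.p_hospitalized) <= 3 * binomial_se(
                stratum.p_hospitalized, hosp.n_obs
            )

    def test_symmetric_half_half_config(self, base_config_module):
        from preecon.parameters import serialize_config

        doc = serialize_config(base_config_module)
        doc["strata"] = {
            "ratio_le_38": {"prevalence": 0.5, "p_hospitalized": 0.5},
            "ratio_38_85": {"prevalence": 0.25, "p_hospitalized": 0.5},
            "ratio_ge_85": {"prevalence": 0.25, "p_hospitalized": 0.5},
        }
        frame = simulate_patients(load_config(doc), "test", 40_000, seed=9)
        estimates = recover_parameters(frame)
        for label in STRATUM_LABELS:
            assert estimates[f"p_hospitalized_{label}"].estimate == pytest.approx(0.5, abs=0.02)

    def test_zero_observation_stratum_flagged(self, test_arm_50k):
        subset = test_arm_50k[test_arm_50k["stratum"] != "ratio_ge_85"]
        estimates = recover_parameters(subset)
        assert not estimates["p_hospitalized_ratio_ge_85"].defined

    def test_no_test_arm_rejected(self, base_config_module):
        frame = simulate_patients(base_config_module, "no_test", 100, seed=1)
        with pytest.raises(ParameterError):
            recover_parameters(frame)

    def test_interval_coverage_across_replicates(self, base_config_module):
        """95% intervals should cover the generating values in >=93% of draws."""
        reps = 50
        hits = {name: 0 for name in ("prevalence", "p_hospitalized")}
        trials = {name: 0 for name in hits}
        for rep in range(reps):
            frame = simulate_patients(base_config_module, "test", 20_000, seed=10_000 + rep)
            estimates = recover_parameters(frame)
            for stratum in base_config_module.strata:
                trials["prevalence"] += 1
                hits["prevalence"] += estimates[f"prevalence_{stratum.label}"].covers(
                    stratum.prevalence
                )
                trials["p_hospitalized"] += 1
                hits["p_hospitalized"] += estimates[f"p_hospitalized_{stratum.label}"].covers(
                    stratum.p_hospitalized
                )
        for name in hits:
            assert hits[name] / trials[name] >= 0.93
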