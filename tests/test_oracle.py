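"""Closed-form expectations, calibration, and the validation harness."""

from dataclasses import replace

import numpy as np
import pytest

import pdcaresim as pc
from pdcaresim.config import Phase, Therapy
from pdcaresim.oracle import (
    CalibrationError,
    CalibrationTargets,
    calibrate,
    expected_phase_occupancy,
    expected_visits,
    validation_report,
)
from pdcaresim.pathway import ScenarioSpec


class TestExpectedVisits:
    def test_mean_doctor_rate_is_caseload_average(self, params):
        # 0.1*1 + 0.6*2.5 + 0.25*3.5 + 0.05*3.5 visits/patient-year
        assert params.mean_rate("doctor") == pytest.approx(2.65)

    def test_baseline_doctor_expectation(self, params):
        exp = expected_visits(params)
        assert exp["doctor_visits"] == pytest.approx(1035 * 3 * 2.65)
        # calibration identity: within a patient of the published 8225
        assert exp["doctor_visits"] == pytest.approx(8225, abs=5)

    def test_therapy_expectations_hit_calibration_targets(self, params):
        exp = expected_visits(params)
        assert exp["physiotherapy_visits"] == pytest.approx(3554)
        assert exp["dietician_visits"] == pytest.approx(434)
        assert exp["total_community_visits"] == pytest.approx(11_910)

    def test_empty_system_is_all_zero(self, params):
        empty = replace(params, run=replace(params.run, prevalent_population=0,
                                            annual_incidence=0.0))
        exp = expected_visits(empty)
        assert all(v == 0 for v in exp.as_dict().values())

    def test_additivity_identities(self, params):
        exp = expected_visits(params)
        assert exp["total_cost"] == pytest.approx(
            exp["total_hospital_cost"] + exp["total_community_cost"]
        )
        assert exp["total_hospital_visits"] == pytest.approx(
            exp["doctor_visits"] + exp["nurse_visits"]
        )

    def test_linearity_in_population_and_horizon(self, params):
        base = expected_visits(params)
        double_pop = replace(params, run=replace(params.run,
                                                 prevalent_population=2 * 1035))
        assert expected_visits(double_pop)["doctor_visits"] == pytest.approx(
            2 * base["doctor_visits"]
        )
        double_years = replace(params, run=replace(params.run, reporting_years=6.0))
        assert expected_visits(double_years)["doctor_visits"] == pytest.approx(
            2 * base["doctor_visits"]
        )

    def test_linearity_in_multipliers(self, params):
        base = expected_visits(params)
        spec = ScenarioSpec(name="x", mode="multiplier",
                            category_multipliers={"doctor": 2.0, "slt": 0.5})
        scaled = expected_visits(params, spec)
        assert scaled["doctor_visits"] == pytest.approx(2 * base["doctor_visits"])
        assert scaled["slt_visits"] == pytest.approx(0.5 * base["slt_visits"])
        assert scaled["nurse_visits"] == pytest.approx(base["nurse_visits"])

    def test_scenario4_multiplier_reproduces_published_doctor_mean(self, params):
        # multiplier 5873/8225 applied to the baseline expectation
        spec = ScenarioSpec(name="s4", mode="multiplier",
                            category_multipliers={"doctor": 5873 / 8225})
        exp = expected_visits(params, spec)
        assert exp["doctor_visits"] == pytest.approx(5873, abs=5)

    def test_mechanistic_mixture(self, params):
        spec = ScenarioSpec(name="m", mode="mechanistic", shift_fraction=0.4,
                            hospital_reduction_factor=0.5,
                            therapy_uplift_factor=1.0)
        base = expected_visits(params)
        exp = expected_visits(params, spec)
        assert exp["doctor_visits"] == pytest.approx(
            (1 - 0.4 * 0.5) * base["doctor_visits"]
        )
        assert exp["physiotherapy_visits"] == pytest.approx(
            (1 + 0.4 * 1.0) * base["physiotherapy_visits"]
        )


class TestCalibration:
    def test_population_from_doctor_target(self, params):
        targets = CalibrationTargets(targets={"doctor_visits": 8225},
                                     free_parameters=["prevalent_population"])
        calibrated = calibrate(params, targets)
        assert calibrated.run.prevalent_population == pytest.approx(8225 / 7.95,
                                                                    rel=1e-9)
        assert expected_visits(calibrated)["doctor_visits"] == pytest.approx(8225)

    def test_physiotherapy_rate_from_visit_target(self, params):
        targets = CalibrationTargets(targets={"physiotherapy_visits": 3554},
                                     free_parameters=["therapy_rate:physiotherapy"])
        calibrated = calibrate(params, targets)
        rate = calibrated.therapy_profiles[Therapy.PHYSIOTHERAPY].visits_per_year
        assert rate == pytest.approx(3554 / (1035 * 0.45 * 3), rel=1e-9)

    def test_recalibration_is_a_fixed_point(self, params):
        targets = CalibrationTargets(
            targets={"doctor_visits": 8225, "physiotherapy_visits": 3554},
            free_parameters=["prevalent_population", "therapy_rate:physiotherapy"],
        )
        once = calibrate(params, targets)
        twice = calibrate(once, targets)
        assert twice.run.prevalent_population == once.run.prevalent_population
        assert (twice.therapy_profiles[Therapy.PHYSIOTHERAPY].visits_per_year
                == once.therapy_profiles[Therapy.PHYSIOTHERAPY].visits_per_year)

    def test_free_parameter_without_target_is_not_identifiable(self, params):
        targets = CalibrationTargets(targets={}, free_parameters=["prevalent_population"])
        with pytest.raises(CalibrationError, match="doctor_visits"):
            calibrate(params, targets)

    def test_infeasible_progression_target(self, params):
        # inflow so large no hazard <= 1 can balance it
        p = replace(params, run=replace(params.run, annual_incidence=10_000.0))
        targets = CalibrationTargets(targets={}, free_parameters=["progression"])
        with pytest.raises(CalibrationError, match="exceeds 1"):
            calibrate(p, targets)

    def test_balanced_progression_hazards(self, params):
        p = replace(params, run=replace(params.run, annual_incidence=5.0))
        calibrated = calibrate(
            p, CalibrationTargets(targets={}, free_parameters=["progression"])
        )
        # flow balance: occupancy x review rate x hazard = inflow, per phase
        n = p.run.prevalent_population
        assert calibrated.progression[Phase.DIAGNOSIS] == pytest.approx(
            5.0 / (n * 0.10 * 1.0)
        )
        assert calibrated.progression[Phase.MAINTENANCE] == pytest.approx(
            5.0 / (n * 0.60 * 2.5)
        )
        assert calibrated.progression[Phase.PALLIATIVE] == 0.0

    def test_balanced_occupancy_stays_near_stationary(self, params):
        p = replace(params, run=replace(params.run, annual_incidence=5.0))
        calibrated = calibrate(
            p, CalibrationTargets(targets={}, free_parameters=["progression"])
        )
        occ_end = expected_phase_occupancy(calibrated, calibrated.run.horizon_years)
        stationary = np.asarray(calibrated.phase_distribution.as_tuple())
        assert np.all(np.abs(occ_end - stationary) <= 0.02)


class TestValidationReport:
    def test_published_validation_differences(self, params):
        report = validation_report(
            params,
            observed={"doctor_visits": 8061, "nurse_visits": 10_875},
            simulated={"doctor_visits": 8225, "nurse_visits": 10_357},
        )
        assert report.loc["doctor_visits", "percent_difference"] == 2
        assert report.loc["nurse_visits", "percent_difference"] == -5

    def test_identical_values_zero_difference(self, params):
        report = validation_report(params, observed={"doctor_visits": 8225},
                                   simulated={"doctor_visits": 8225})
        assert report.loc["doctor_visits", "percent_difference"] == 0

    def test_nonpositive_observed_rejected(self, params):
        with pytest.raises(ValueError):
            validation_report(params, observed={"doctor_visits": 0},
                              simulated={"doctor_visits": 1})
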