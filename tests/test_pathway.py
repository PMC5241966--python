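"""Disease and care logic: populations, arrivals, consultations, scenarios."""

from dataclasses import replace

import numpy as np
import pytest

import pdcaresim as pc
from pdcaresim.config import Phase, PhaseDistribution, Therapy
from pdcaresim.engine import EventKind
from pdcaresim.pathway import (
    Patient,
    ScenarioSpec,
    apply_scenario,
    assign_therapies,
    generate_arrivals,
    initialize_population,
    progress_phase,
    sample_visit_rate,
    schedule_consultations,
    therapy_visit_events,
)


def _patient(**kwargs) -> Patient:
    defaults = dict(id=0, referral_source="gp", phase=Phase.MAINTENANCE,
                    entry_time=0.0, doctor_rate=2.5, nurse_rate=3.0)
    defaults.update(kwargs)
    return Patient(**defaults)


class TestInitializePopulation:
    def test_phase_mix_converges_to_distribution(self, params, rng):
        big = replace(params, run=replace(params.run, prevalent_population=10_000))
        population = initialize_population(big, rng)
        maintenance = sum(p.phase is Phase.MAINTENANCE for p in population)
        sigma = np.sqrt(10_000 * 0.6 * 0.4)
        assert abs(maintenance - 6000) < 3 * sigma

    def test_zero_population_is_empty(self, params, rng):
        none = replace(params, run=replace(params.run, prevalent_population=0))
        assert initialize_population(none, rng) == []

    def test_all_diagnosis_distribution_pins_doctor_rate(self, params, rng):
        all_diag = replace(
            params,
            phase_distribution=PhaseDistribution(1.0, 0.0, 0.0, 0.0),
            run=replace(params.run, prevalent_population=200),
        )
        population = initialize_population(all_diag, rng)
        assert all(p.phase is Phase.DIAGNOSIS for p in population)
        assert all(p.doctor_rate == 1.0 for p in population)

    def test_rates_fall_within_phase_ranges(self, params, rng):
        population = initialize_population(
            replace(params, run=replace(params.run, prevalent_population=500)), rng
        )
        for patient in population:
            profile = params.phase_profiles[patient.phase]
            lo, hi = profile.doctor_visits_per_year
            assert lo <= patient.doctor_rate <= hi
            lo, hi = profile.nurse_visits_per_year
            assert lo <= patient.nurse_rate <= hi

    def test_palliative_patients_seen_monthly_by_nurse(self, params, rng):
        all_pall = replace(
            params,
            phase_distribution=PhaseDistribution(0.0, 0.0, 0.0, 1.0),
            run=replace(params.run, prevalent_population=50),
        )
        population = initialize_population(all_pall, rng)
        assert all(p.nurse_rate == 12.0 for p in population)


class TestArrivals:
    def test_zero_incidence_no_arrivals(self, params, rng):
        assert generate_arrivals(params, rng) == []

    def test_poisson_count_over_horizon(self, params, rng):
        p = replace(params, run=replace(params.run, annual_incidence=100.0))
        events = generate_arrivals(p, rng, horizon=4.0)
        assert abs(len(events) - 400) < 3 * np.sqrt(400)
        assert all(0 <= e.time < 4.0 for e in events)
        assert all(e.kind == EventKind.ARRIVAL for e in events)

    def test_referral_mix_share(self, params, rng):
        p = replace(params, run=replace(params.run, annual_incidence=2500.0))
        events = generate_arrivals(p, rng, horizon=4.0)
        share = np.mean([e.payload["referral_source"] == "gp" for e in events])
        sigma = np.sqrt(0.75 * 0.25 / len(events))
        assert abs(share - 0.75) < 3 * sigma


class TestVisitRateSampling:
    def test_degenerate_ranges_are_exact(self, params, rng):
        assert sample_visit_rate(params.phase_profiles[Phase.DIAGNOSIS],
                                 "doctor", rng) == 1.0
        assert sample_visit_rate(params.phase_profiles[Phase.PALLIATIVE],
                                 "nurse", rng) == 12.0

    def test_uniform_mean_on_maintenance_range(self, params, rng):
        profile = params.phase_profiles[Phase.MAINTENANCE]
        draws = [sample_visit_rate(profile, "doctor", rng) for _ in range(10_000)]
        assert all(2.0 <= d <= 3.0 for d in draws)
        sigma_mean = (1 / np.sqrt(12)) / np.sqrt(10_000)
        assert abs(np.mean(draws) - 2.5) < 3 * sigma_mean


class TestConsultationScheduling:
    def test_zero_rate_schedules_nothing(self, rng):
        patient = _patient(doctor_rate=0.0, nurse_rate=0.0)
        assert schedule_consultations(patient, until=3.0, rng=rng) == []

    def test_poisson_mean_matches_rate_times_horizon(self, rng):
        counts = []
        for i in range(1000):
            patient = _patient(id=i, doctor_rate=2.65, nurse_rate=0.0)
            events = schedule_consultations(patient, until=3.0, rng=rng)
            counts.append(len(events))
        sigma_mean = np.sqrt(7.95 / 1000)
        assert abs(np.mean(counts) - 2.65 * 3.0) < 3 * sigma_mean

    def test_events_respect_time_bounds(self, rng):
        patient = _patient(entry_time=1.25, doctor_rate=5.0, nurse_rate=4.0)
        events = schedule_consultations(patient, until=3.5, rng=rng)
        assert all(1.25 <= e.time < 3.5 for e in events)

    def test_fixed_interval_mode_is_regular(self, rng):
        patient = _patient(doctor_rate=4.0, nurse_rate=0.0)
        events = schedule_consultations(patient, until=2.0, rng=rng,
                                        model="fixed_interval")
        gaps = np.diff([e.time for e in events])
        assert np.allclose(gaps, 0.25)

    def test_therapy_visits_only_for_assigned_therapies(self, rng):
        patient = _patient(therapies={Therapy.PHYSIOTHERAPY: 2.5})
        events = therapy_visit_events(patient, until=4.0, rng=rng)
        assert events
        assert {e.payload["therapy"] for e in events} == {"physiotherapy"}


class TestProgression:
    def test_zero_hazard_never_progresses(self, params, rng):
        patient = _patient(phase=Phase.DIAGNOSIS, doctor_rate=1.0)
        for _ in range(50):
            progress_phase(patient, params, rng)
        assert patient.phase is Phase.DIAGNOSIS

    def test_forced_progression_moves_one_phase_and_resamples(self, params, rng):
        p = replace(params, progression={Phase.DIAGNOSIS: 1.0, Phase.MAINTENANCE: 0.0,
                                         Phase.COMPLEX: 0.0, Phase.PALLIATIVE: 0.0})
        patient = _patient(phase=Phase.DIAGNOSIS, doctor_rate=1.0, nurse_rate=3.0)
        progress_phase(patient, p, rng)
        assert patient.phase is Phase.MAINTENANCE
        assert 2.0 <= patient.doctor_rate <= 3.0
        assert 2.0 <= patient.nurse_rate <= 4.0
        assert patient.nurse_generation == 1

    def test_palliative_is_absorbing(self, params, rng):
        p = replace(params, progression={ph: 0.0 for ph in Phase})
        forced = replace(p, progression={**p.progression, Phase.COMPLEX: 1.0})
        patient = _patient(phase=Phase.COMPLEX, doctor_rate=3.5)
        progress_phase(patient, forced, rng)
        assert patient.phase is Phase.PALLIATIVE
        assert patient.nurse_rate == 12.0
        for _ in range(20):
            progress_phase(patient, forced, rng)
        assert patient.phase is Phase.PALLIATIVE


class TestTherapyAssignment:
    def test_zero_probabilities_empty_set(self, params, rng):
        profiles = {
            th: replace(prof, usage_probability=0.0)
            for th, prof in params.therapy_profiles.items()
        }
        p = replace(params, therapy_profiles=profiles)
        patient = assign_therapies(_patient(), p, rng)
        assert patient.therapies == {}

    def test_mean_therapies_per_patient(self, params, rng):
        counts = [
            len(assign_therapies(_patient(id=i), params, rng).therapies)
            for i in range(10_000)
        ]
        variance = sum(u * (1 - u) for u in
                       (t.usage_probability for t in params.therapy_profiles.values()))
        sigma_mean = np.sqrt(variance / 10_000)
        assert abs(np.mean(counts) - 1.60) < 3 * sigma_mean

    def test_no_community_referral_no_therapies(self, params, rng):
        p = replace(params, community_referral_probability=0.0)
        patient = assign_therapies(_patient(), p, rng)
        assert patient.therapies == {}


class TestScenarios:
    def test_zero_shift_is_identity(self, rng):
        spec = ScenarioSpec(name="none", mode="mechanistic", shift_fraction=0.0)
        patient = _patient(therapies={Therapy.SLT: 2.5})
        before = (patient.doctor_rate, patient.nurse_rate, dict(patient.therapies))
        apply_scenario([patient], spec, rng)
        assert (patient.doctor_rate, patient.nurse_rate, patient.therapies) == before
        assert not patient.community_managed

    def test_full_shift_full_reduction_removes_hospital_visits(self, params):
        spec = ScenarioSpec(name="all-community", mode="mechanistic",
                            shift_fraction=1.0, hospital_reduction_factor=1.0)
        small = replace(params, run=replace(params.run, prevalent_population=100))
        result = pc.run_replication(small, spec, seed=3)
        assert result.ledger.total_hospital_visits == 0
        assert result.ledger.total_community_visits > 0

    def test_multiplier_scales_rates(self, rng):
        spec = ScenarioSpec(name="m", mode="multiplier",
                            category_multipliers={"doctor": 0.714, "slt": 2.0})
        patient = _patient(doctor_rate=2.0, nurse_rate=3.0,
                           therapies={Therapy.SLT: 2.5})
        apply_scenario([patient], spec, rng)
        assert patient.doctor_rate == pytest.approx(2.0 * 0.714)
        assert patient.nurse_rate == 3.0
        assert patient.therapies[Therapy.SLT] == pytest.approx(5.0)

    def test_unknown_multiplier_category_rejected(self):
        spec = ScenarioSpec(name="bad", mode="multiplier",
                            category_multipliers={"surgeon": 2.0})
        with pytest.raises(ValueError, match="surgeon"):
            spec.validate()

    def test_shipped_scenarios_reproduce_published_ratios(self, scenarios):
        s4 = scenarios["scenario_4"]
        assert s4.multiplier("doctor") == pytest.approx(5873 / 8225)
        assert s4.multiplier("physiotherapy") == pytest.approx(6755 / 3554)
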