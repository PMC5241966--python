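"""Disease and care-pathway logic.

Covers everything between the event kernel and the ledgers: prevalent-
population initialization, Poisson referral arrivals, phase assignment and
progression, per-patient consultation scheduling, community-therapy
assignment, and scenario application.

Modelling choices
-----------------
Consultations are Poisson processes at each patient's personal annual rate
(drawn uniformly from the phase profile's range), not rigid fixed-interval
appointments: the source frequencies are ranges ("2 to 3 times a year"),
and rate-based scheduling makes the analytic expectations exact.  A
``fixed_interval`` consultation model is available as a config switch.

Phase progression happens only at doctor reviews: with the configured
per-phase hazard the patient advances one phase (Diagnosis -> Maintenance
-> Complex -> Palliative, the last absorbing) and redraws their
consultation rates from the new phase's profile.

Scenarios come in two modes.  ``multiplier`` mode scales every patient's
per-category visit rates by published effect ratios and is how the four
community-shift scenarios ship.  ``mechanistic`` mode selects each patient
independently with probability ``shift_fraction`` for community management,
scaling their hospital consultation rates down by ``hospital_reduction_factor``
and their therapy rates up by ``therapy_uplift_factor`` — a prospective
what-if rule rather than a reproduction of published effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from . import reference
from .config import (
    PHASE_ORDER,
    REFERRAL_SOURCES,
    ParameterSet,
    Phase,
    PhaseProfile,
    Therapy,
)
from .engine import STREAM_NAMES, Event, EventKind

__all__ = [
    "Patient",
    "ScenarioSpec",
    "baseline_scenario",
    "default_scenarios",
    "initialize_population",
    "generate_arrivals",
    "sample_visit_rate",
    "schedule_consultations",
    "therapy_visit_events",
    "progress_phase",
    "assign_therapies",
    "apply_scenario",
    "PathwayState",
]

#: Scenario multiplier categories: the two hospital roles plus each therapy.
SCENARIO_CATEGORIES: tuple[str, ...] = (
    "doctor", "nurse", *(th.value for th in Therapy),
)


@dataclass
class Patient:
    """One individual moving through the care system.

    ``doctor_rate`` / ``nurse_rate`` and the per-therapy rates are
    *effective* annual visit rates (base rate times any scenario scaling);
    the scale factors are kept so rates can be re-derived when progression
    resamples the base rate.
    """

    id: int
    referral_source: str
    phase: Phase
    entry_time: float
    doctor_rate: float
    nurse_rate: float
    therapies: dict[Therapy, float] = field(default_factory=dict)
    community_managed: bool = False
    doctor_scale: float = 1.0
    nurse_scale: float = 1.0
    nurse_generation: int = 0


@dataclass(frozen=True)
class ScenarioSpec:
    """A named intervention shifting care from hospital to community.

    Exactly one mode's fields are consulted: ``category_multipliers`` in
    ``multiplier`` mode; ``shift_fraction`` / ``hospital_reduction_factor``
    / ``therapy_uplift_factor`` in ``mechanistic`` mode.
    """

    name: str
    mode: str = "multiplier"
    shift_fraction: float = 0.0
    hospital_reduction_factor: float = 0.5
    therapy_uplift_factor: float = 1.0
    category_multipliers: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.mode not in ("multiplier", "mechanistic"):
            raise ValueError(f"scenario mode must be 'multiplier' or "
                             f"'mechanistic', got {self.mode!r}")
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must lie in [0, 1]")
        if self.hospital_reduction_factor < 0 or self.therapy_uplift_factor < 0:
            raise ValueError("scenario factors must be >= 0")
        if self.mode == "multiplier" and self.category_multipliers:
            unknown = set(self.category_multipliers) - set(SCENARIO_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown multiplier categories: {sorted(unknown)}")

    def multiplier(self, category: str) -> float:
        if self.category_multipliers is None:
            return 1.0
        return float(self.category_multipliers.get(category, 1.0))


def baseline_scenario() -> ScenarioSpec:
    """The do-nothing scenario (all multipliers 1)."""
    return ScenarioSpec(name="baseline")


def default_scenarios() -> dict[str, ScenarioSpec]:
    """Baseline plus the four shipped community-shift scenarios.

    The shipped scenarios are multiplier-mode: their per-category
    multipliers are the ratios of the published scenario activity means to
    the baseline means (the verbal 10/20/40/50% shift rules alone do not
    determine the published per-category effects).
    """
    scenarios = {"baseline": baseline_scenario()}
    shift = {"scenario_1": 0.1, "scenario_2": 0.2,
             "scenario_3": 0.4, "scenario_4": 0.5}
    for name, frac in shift.items():
        scenarios[name] = ScenarioSpec(
            name=name,
            mode="multiplier",
            shift_fraction=frac,
            category_multipliers=reference.scenario_multipliers(name),
        )
    return scenarios


# ---------------------------------------------------------------------------
# sampling helpers


def _as_streams(rng) -> Mapping[str, np.random.Generator]:
    """Accept either a mapping of named streams or a single generator."""
    if isinstance(rng, Mapping):
        return rng
    return {name: rng for name in STREAM_NAMES}


def sample_visit_rate(profile: PhaseProfile, role: str,
                      rng: np.random.Generator) -> float:
    """Draw a personal visit rate uniformly from the closed range for
    ``role`` in this phase; degenerate ranges return the pinned value
    without consuming randomness."""
    lo, hi = profile.rate_range(role)
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


def _sample_categorical(rng: np.random.Generator, labels, probs) -> str:
    u = rng.random()
    acc = 0.0
    for label, prob in zip(labels, probs):
        acc += prob
        if u < acc:
            return label
    return labels[-1]


def _first_gap(rng: np.random.Generator, rate: float, model: str) -> float:
    if model == "fixed_interval":
        # uniform phase offset: the stationary (equilibrium) renewal start
        return float(rng.uniform(0.0, 1.0 / rate))
    return float(rng.exponential(1.0 / rate))


def _next_gap(rng: np.random.Generator, rate: float, model: str) -> float:
    if model == "fixed_interval":
        return 1.0 / rate
    return float(rng.exponential(1.0 / rate))


# ---------------------------------------------------------------------------
# patient construction


def assign_therapies(patient: Patient, p: ParameterSet, rng) -> Patient:
    """Assign community therapies to ``patient``.

    With probability ``community_referral_probability`` the patient is
    referred to community services; each therapy is then included
    independently with its usage probability, at the profile's annual
    visit rate.
    """
    streams = _as_streams(rng)
    trng = streams["therapy"]
    patient.therapies = {}
    if trng.random() < p.community_referral_probability:
        for th in Therapy:
            prof = p.therapy_profiles[th]
            if trng.random() < prof.usage_probability:
                patient.therapies[th] = prof.visits_per_year
    return patient


def _apply_scenario_to_patient(patient: Patient, s: ScenarioSpec, u: float) -> None:
    if s.mode == "multiplier":
        patient.doctor_scale *= s.multiplier("doctor")
        patient.nurse_scale *= s.multiplier("nurse")
        patient.doctor_rate *= s.multiplier("doctor")
        patient.nurse_rate *= s.multiplier("nurse")
        for th in list(patient.therapies):
            patient.therapies[th] *= s.multiplier(th.value)
    else:  # mechanistic
        if u < s.shift_fraction:
            patient.community_managed = True
            keep = 1.0 - s.hospital_reduction_factor
            up = 1.0 + s.therapy_uplift_factor
            patient.doctor_scale *= keep
            patient.nurse_scale *= keep
            patient.doctor_rate *= keep
            patient.nurse_rate *= keep
            for th in list(patient.therapies):
                patient.therapies[th] *= up


def apply_scenario(population: Iterable[Patient], s: ScenarioSpec, rng) -> list[Patient]:
    """Apply a scenario to an existing population (in patient order, one
    selection draw per patient so scenarios share randomness)."""
    s.validate()
    streams = _as_streams(rng)
    srng = streams["scenario"]
    population = list(population)
    for patient in population:
        _apply_scenario_to_patient(patient, s, srng.random())
    return population


def _create_patient(p: ParameterSet, pid: int, entry_time: float,
                    referral_source: str, phase: Phase, streams,
                    scenario: ScenarioSpec | None) -> Patient:
    arng = streams["attributes"]
    profile = p.phase_profiles[phase]
    patient = Patient(
        id=pid,
        referral_source=referral_source,
        phase=phase,
        entry_time=entry_time,
        doctor_rate=sample_visit_rate(profile, "doctor", arng),
        nurse_rate=sample_visit_rate(profile, "nurse", arng),
    )
    assign_therapies(patient, p, streams)
    u = streams["scenario"].random()  # always drawn, for cross-scenario alignment
    if scenario is not None:
        _apply_scenario_to_patient(patient, scenario, u)
    return patient


def initialize_population(p: ParameterSet, rng,
                          scenario: ScenarioSpec | None = None) -> list[Patient]:
    """Create the prevalent caseload at t=0.

    Phases are drawn from the stationary phase distribution, referral
    sources from the referral mix, personal visit rates from the phase
    profiles, and therapies per the usage probabilities; the scenario (if
    given) is applied at creation.
    """
    streams = _as_streams(rng)
    arng = streams["attributes"]
    mix = p.referral_mix.as_tuple()
    dist = p.phase_distribution.as_tuple()
    population = []
    for pid in range(p.run.prevalent_population):
        source = _sample_categorical(arng, REFERRAL_SOURCES, mix)
        phase = Phase(_sample_categorical(arng, [ph.value for ph in PHASE_ORDER], dist))
        population.append(
            _create_patient(p, pid, 0.0, source, phase, streams, scenario)
        )
    return population


def generate_arrivals(p: ParameterSet, rng, horizon: float | None = None) -> list[Event]:
    """Homogeneous Poisson referral arrivals over the full run, each tagged
    with a referral source drawn from the referral mix."""
    streams = _as_streams(rng)
    arng = streams["arrivals"]
    rate = p.run.annual_incidence
    if horizon is None:
        horizon = p.run.horizon_years
    events: list[Event] = []
    if rate <= 0.0:
        return events
    mix = p.referral_mix.as_tuple()
    t = float(arng.exponential(1.0 / rate))
    while t < horizon:
        source = _sample_categorical(arng, REFERRAL_SOURCES, mix)
        events.append(Event(t, EventKind.ARRIVAL, payload={"referral_source": source}))
        t += float(arng.exponential(1.0 / rate))
    return events


# ---------------------------------------------------------------------------
# per-patient event generation (stand-alone forms used in tests and by the
# fixed-horizon pre-generation paths)


def schedule_consultations(patient: Patient, until: float, rng,
                           model: str = "poisson",
                           start: float | None = None) -> list[Event]:
    """Generate this patient's doctor-review and nurse-visit events as
    independent Poisson processes at their current rates, from ``start``
    (default: entry time) to ``until``."""
    streams = _as_streams(rng)
    t0 = patient.entry_time if start is None else start
    events: list[Event] = []
    for role, rate, kind, rng_name in (
        ("doctor", patient.doctor_rate, EventKind.DOCTOR_REVIEW, "consult_doctor"),
        ("nurse", patient.nurse_rate, EventKind.NURSE_VISIT, "consult_nurse"),
    ):
        if rate <= 0.0:
            continue
        grng = streams[rng_name]
        t = t0 + _first_gap(grng, rate, model)
        while t < until:
            payload = {"generation": patient.nurse_generation} if role == "nurse" else None
            events.append(Event(t, kind, patient_id=patient.id, payload=payload))
            t += _next_gap(grng, rate, model)
    events.sort(key=lambda e: e.time)
    return events


def therapy_visit_events(patient: Patient, until: float, rng,
                         model: str = "poisson",
                         start: float | None = None) -> list[Event]:
    """Generate the patient's community-therapy visits as independent
    Poisson processes at the assigned per-therapy rates."""
    streams = _as_streams(rng)
    grng = streams["consult_therapy"]
    t0 = patient.entry_time if start is None else start
    events: list[Event] = []
    for th, rate in patient.therapies.items():
        if rate <= 0.0:
            continue
        t = t0 + _first_gap(grng, rate, model)
        while t < until:
            events.append(Event(t, EventKind.THERAPY_VISIT, patient_id=patient.id,
                                payload={"therapy": th.value}))
            t += _next_gap(grng, rate, model)
    events.sort(key=lambda e: e.time)
    return events


def progress_phase(patient: Patient, p: ParameterSet, rng) -> Patient:
    """Advance the patient one phase with the configured per-review hazard.

    Called at doctor reviews.  On progression the patient's personal
    consultation rates are redrawn from the new phase's profile (scenario
    scaling preserved) and any pending nurse schedule is invalidated via
    the generation counter.  Palliative is absorbing.
    """
    streams = _as_streams(rng)
    hazard = p.progression.get(patient.phase, 0.0)
    if hazard <= 0.0 or patient.phase is Phase.PALLIATIVE:
        return patient
    if streams["progression"].random() >= hazard:
        return patient
    next_phase = PHASE_ORDER[PHASE_ORDER.index(patient.phase) + 1]
    patient.phase = next_phase
    profile = p.phase_profiles[next_phase]
    arng = streams["attributes"]
    patient.doctor_rate = sample_visit_rate(profile, "doctor", arng) * patient.doctor_scale
    patient.nurse_rate = sample_visit_rate(profile, "nurse", arng) * patient.nurse_scale
    patient.nurse_generation += 1
    return patient


# ---------------------------------------------------------------------------
# event-driven state machine used by the engine


class PathwayState:
    """Mutable pathway state for one replication: the patient registry and
    the event handlers invoked by :func:`pdcaresim.engine.run_replication`."""

    def __init__(self, p: ParameterSet, scenario: ScenarioSpec, streams) -> None:
        self.p = p
        self.scenario = scenario
        self.streams = _as_streams(streams)
        self.patients: dict[int, Patient] = {}
        self._next_id = 0

    def register(self, patient: Patient) -> None:
        self.patients[patient.id] = patient
        self._next_id = max(self._next_id, patient.id + 1)

    # -- event construction -------------------------------------------------

    def _consult_event(self, patient: Patient, role: str, t_from: float,
                       horizon: float, first: bool) -> Event | None:
        rate = patient.doctor_rate if role == "doctor" else patient.nurse_rate
        if rate <= 0.0:
            return None
        grng = self.streams["consult_doctor" if role == "doctor" else "consult_nurse"]
        model = self.p.consultation_model
        gap = _first_gap(grng, rate, model) if first else _next_gap(grng, rate, model)
        t = t_from + gap
        if t >= horizon:
            return None
        if role == "doctor":
            return Event(t, EventKind.DOCTOR_REVIEW, patient_id=patient.id)
        return Event(t, EventKind.NURSE_VISIT, patient_id=patient.id,
                     payload={"generation": patient.nurse_generation})

    def _therapy_event(self, patient: Patient, therapy: Therapy, t_from: float,
                       horizon: float, first: bool) -> Event | None:
        rate = patient.therapies.get(therapy, 0.0)
        if rate <= 0.0:
            return None
        grng = self.streams["consult_therapy"]
        model = self.p.consultation_model
        gap = _first_gap(grng, rate, model) if first else _next_gap(grng, rate, model)
        t = t_from + gap
        if t >= horizon:
            return None
        return Event(t, EventKind.THERAPY_VISIT, patient_id=patient.id,
                     payload={"therapy": therapy.value})

    def initial_events(self, patient: Patient, horizon: float) -> list[Event]:
        """First doctor, nurse, and therapy events after a patient enters."""
        t0 = patient.entry_time
        events = []
        for role in ("doctor", "nurse"):
            ev = self._consult_event(patient, role, t0, horizon, first=True)
            if ev is not None:
                events.append(ev)
        for th in patient.therapies:
            ev = self._therapy_event(patient, th, t0, horizon, first=True)
            if ev is not None:
                events.append(ev)
        return events

    # -- event handlers -----------------------------------------------------

    def on_arrival(self, event: Event, horizon: float) -> list[Event]:
        t_diag = event.time + self.p.diagnosis_delay_years
        patient = _create_patient(
            self.p, self._next_id, t_diag,
            event.payload["referral_source"], Phase.DIAGNOSIS,
            self.streams, self.scenario,
        )
        self.register(patient)
        events: list[Event] = []
        if t_diag < horizon:
            events.append(Event(t_diag, EventKind.DIAGNOSIS, patient_id=patient.id))
            events.extend(self.initial_events(patient, horizon))
        return events

    def on_doctor_review(self, event: Event, horizon: float) -> list[Event]:
        patient = self.patients[event.patient_id]
        phase_before = patient.phase
        progress_phase(patient, self.p, self.streams)
        events: list[Event] = []
        if patient.phase is not phase_before:
            events.append(Event(event.time, EventKind.PHASE_CHANGE,
                                patient_id=patient.id,
                                payload={"from": phase_before.value,
                                         "to": patient.phase.value}))
            ev = self._consult_event(patient, "nurse", event.time, horizon, first=True)
            if ev is not None:
                events.append(ev)
        ev = self._consult_event(patient, "doctor", event.time, horizon, first=False)
        if ev is not None:
            events.append(ev)
        return events

    def on_nurse_visit(self, event: Event, horizon: float) -> list[Event] | None:
        """Returns None if the event belongs to a superseded schedule."""
        patient = self.patients[event.patient_id]
        if event.payload["generation"] != patient.nurse_generation:
            return None
        ev = self._consult_event(patient, "nurse", event.time, horizon, first=False)
        return [ev] if ev is not None else []

    def on_therapy_visit(self, event: Event, horizon: float) -> list[Event]:
        patient = self.patients[event.patient_id]
        th = Therapy(event.payload["therapy"])
        ev = self._therapy_event(patient, th, event.time, horizon, first=False)
        return [ev] if ev is not None else []
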