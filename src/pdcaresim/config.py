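"""Model configuration: typed parameter structures, defaults, validation, I/O.

Every quantity the simulation consumes lives in a single immutable
:class:`ParameterSet`: the referral mix of newly diagnosed patients, the
disease-phase distribution, per-phase consultation frequency ranges,
community-therapy usage and visit rates, unit costs, staffing capacity
constants, progression hazards, and the run design (warm-up, reporting
horizon, replications).

The default fixture (:func:`default_parameters`) is calibrated so that the
analytic expectation of every baseline activity indicator reproduces the
study Trust's published baseline levels (see :mod:`pdcaresim.reference`).
Configs are stored as YAML; unknown keys are a hard error so that a typo in
a rate name cannot silently corrupt a run.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import reference

__all__ = [
    "Phase",
    "Therapy",
    "ReferralMix",
    "PhaseDistribution",
    "PhaseProfile",
    "TherapyProfile",
    "CostSchedule",
    "StaffingSchedule",
    "RunConfig",
    "ParameterSet",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "parameter_digest",
    "guideline_phase_profiles",
    "background_unit_costs",
]

_SUM_TOL = 1e-9


class ParameterError(ValueError):
    """Raised for unreadable, malformed, or invariant-violating configs."""


class Phase(str, enum.Enum):
    """Successive, non-reversible phases of Parkinson's disease."""

    DIAGNOSIS = "diagnosis"
    MAINTENANCE = "maintenance"
    COMPLEX = "complex"
    PALLIATIVE = "palliative"


PHASE_ORDER: tuple[Phase, ...] = (
    Phase.DIAGNOSIS,
    Phase.MAINTENANCE,
    Phase.COMPLEX,
    Phase.PALLIATIVE,
)


class Therapy(str, enum.Enum):
    """Community-service therapies available to PD patients."""

    PHYSIOTHERAPY = "physiotherapy"
    SLT = "slt"  # speech and language therapy
    PSYCHIATRY = "psychiatry"
    OCCUPATIONAL = "occupational"
    PALLIATIVE_CARE = "palliative_care"
    DIETICIAN = "dietician"


THERAPY_ORDER: tuple[Therapy, ...] = tuple(Therapy)

REFERRAL_SOURCES: tuple[str, ...] = ("gp", "ae", "outpatient", "other_hospital")


@dataclass(frozen=True)
class ReferralMix:
    """Proportions of new patients by referral source; must sum to 1."""

    gp: float = 0.75
    ae: float = 0.15
    outpatient: float = 0.05
    other_hospital: float = 0.05

    def as_tuple(self) -> tuple[float, ...]:
        return (self.gp, self.ae, self.outpatient, self.other_hospital)


@dataclass(frozen=True)
class PhaseDistribution:
    """Stationary share of the caseload in each disease phase; sums to 1."""

    diagnosis: float = 0.10
    maintenance: float = 0.60
    complex: float = 0.25
    palliative: float = 0.05

    def as_tuple(self) -> tuple[float, ...]:
        return (self.diagnosis, self.maintenance, self.complex, self.palliative)

    def share(self, phase: Phase) -> float:
        return getattr(self, phase.value)


@dataclass(frozen=True)
class PhaseProfile:
    """Consultation frequency ranges (visits/year) for one disease phase.

    A patient entering the phase draws their personal doctor and nurse visit
    rates uniformly from the closed ranges; degenerate ranges (min == max)
    pin the rate exactly.
    """

    phase: Phase
    doctor_visits_per_year: tuple[float, float]
    nurse_visits_per_year: tuple[float, float]

    def rate_range(self, role: str) -> tuple[float, float]:
        if role == "doctor":
            return self.doctor_visits_per_year
        if role == "nurse":
            return self.nurse_visits_per_year
        raise ValueError(f"unknown role {role!r}")

    def mean_rate(self, role: str) -> float:
        lo, hi = self.rate_range(role)
        return (lo + hi) / 2.0


@dataclass(frozen=True)
class TherapyProfile:
    """Uptake probability, visit rate, and unit cost of one therapy."""

    therapy: Therapy
    usage_probability: float
    visits_per_year: float
    unit_cost: float


@dataclass(frozen=True)
class CostSchedule:
    """Per-visit unit costs in GBP.

    ``therapy_unit_costs`` is assembled from the therapy profiles and is not
    an independent degree of freedom.  The emergency admission cost is an
    inert hook: admissions are not simulated (``emergency_admission_rate``
    defaults to 0 and has no downstream effect).
    """

    doctor_visit_cost: float
    nurse_visit_cost: float
    emergency_admission_cost: float = 2133.0
    therapy_unit_costs: Mapping[Therapy, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StaffingSchedule:
    """Workload-to-staffing conversion constants.

    Service hours equal visits times hours-per-visit; FTEs equal hours
    divided by the hours one full-time contract supplies over one reporting
    window (a "run").
    """

    hours_per_doctor_visit: float = 1.0
    hours_per_nurse_visit: float = 1.0
    doctor_hours_per_fte_per_run: float = 0.0  # filled by default_parameters
    nurse_hours_per_fte_per_run: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Run design: horizon, replication count, caseload size.

    ``annual_incidence`` is the *net* inflow of new patients per year
    (incident diagnoses net of deaths and transfers, which are not modelled
    separately); the default 0 keeps the caseload constant, matching the
    study Trust's observation that the phase mix is essentially stationary.
    """

    warmup_years: float = 1.0
    reporting_years: float = 3.0
    n_replications: int = 100
    master_seed: int = 12345
    prevalent_population: int = 0  # filled by default_parameters
    annual_incidence: float = 0.0

    @property
    def horizon_years(self) -> float:
        return self.warmup_years + self.reporting_years


@dataclass(frozen=True)
class ParameterSet:
    """The complete, immutable model configuration."""

    referral_mix: ReferralMix
    phase_distribution: PhaseDistribution
    phase_profiles: Mapping[Phase, PhaseProfile]
    therapy_profiles: Mapping[Therapy, TherapyProfile]
    community_referral_probability: float
    cost_schedule: CostSchedule
    staffing: StaffingSchedule
    run: RunConfig
    #: per-phase probability that a doctor review advances the patient one
    #: phase (Diagnosis -> Maintenance -> Complex -> Palliative; Palliative
    #: is absorbing and must have hazard 0)
    progression: Mapping[Phase, float]
    #: "poisson" (rate-based, default) or "fixed_interval" consultations
    consultation_model: str = "poisson"
    #: delay between arrival and confirmed diagnosis, years (default: none)
    diagnosis_delay_years: float = 0.0
    #: inert hook, not simulated; kept at 0
    emergency_admission_rate: float = 0.0

    def mean_rate(self, role: str) -> float:
        """Caseload-average visits/patient-year for ``role`` under the
        stationary phase mix (e.g. 2.65 for doctors under the defaults)."""
        return sum(
            self.phase_distribution.share(ph) * self.phase_profiles[ph].mean_rate(role)
            for ph in PHASE_ORDER
        )


# ---------------------------------------------------------------------------
# defaults


def _default_phase_profiles() -> dict[Phase, PhaseProfile]:
    # Trust-observed consultation frequencies: doctors once a year at
    # Diagnosis, 2-3/yr Maintenance, 3-4/yr Complex and Palliative; nurses
    # 2-4/yr except monthly in the Palliative phase.
    return {
        Phase.DIAGNOSIS: PhaseProfile(Phase.DIAGNOSIS, (1.0, 1.0), (2.0, 4.0)),
        Phase.MAINTENANCE: PhaseProfile(Phase.MAINTENANCE, (2.0, 3.0), (2.0, 4.0)),
        Phase.COMPLEX: PhaseProfile(Phase.COMPLEX, (3.0, 4.0), (2.0, 4.0)),
        Phase.PALLIATIVE: PhaseProfile(Phase.PALLIATIVE, (3.0, 4.0), (12.0, 12.0)),
    }


def guideline_phase_profiles() -> dict[Phase, PhaseProfile]:
    """National-guideline consultation frequencies (2, 4, 5, 6 visits/year
    across the four phases, both roles) as an alternative to the
    Trust-observed default profile."""
    freqs = {Phase.DIAGNOSIS: 2.0, Phase.MAINTENANCE: 4.0,
             Phase.COMPLEX: 5.0, Phase.PALLIATIVE: 6.0}
    return {
        ph: PhaseProfile(ph, (f, f), (f, f)) for ph, f in freqs.items()
    }


_THERAPY_USAGE = {
    Therapy.PHYSIOTHERAPY: 0.45,
    Therapy.SLT: 0.425,
    Therapy.OCCUPATIONAL: 0.35,
    Therapy.PSYCHIATRY: 0.225,
    Therapy.DIETICIAN: 0.075,
    Therapy.PALLIATIVE_CARE: 0.075,
}

# Unit costs implied by the Trust's cost and activity tables (cost / visits,
# all exact integer divisions).  The national reference-cost quotes round
# SLT to 98 and occupational therapy to 56; those ship as the alternative
# profile below.
_TABLE_UNIT_COSTS = {
    "doctor": 220.0,
    "nurse": 150.0,
    Therapy.PHYSIOTHERAPY: 38.0,
    Therapy.SLT: 96.0,
    Therapy.PSYCHIATRY: 50.0,
    Therapy.OCCUPATIONAL: 58.0,
    Therapy.PALLIATIVE_CARE: 50.0,
    Therapy.DIETICIAN: 50.0,
}

_BACKGROUND_UNIT_COSTS = {
    Therapy.PHYSIOTHERAPY: 38.0,
    Therapy.OCCUPATIONAL: 56.0,
    Therapy.SLT: 98.0,
}


def default_parameters() -> ParameterSet:
    """The calibrated default fixture for the study Trust.

    Calibration identities (all against the baseline activity column in
    :mod:`pdcaresim.reference`):

    * prevalent population = doctor visits / (reporting years x mean doctor
      rate) = 8225 / (3 x 2.65), rounded to a whole patient count (1035);
    * each therapy's visits/year = baseline therapy visits /
      (population x usage probability x reporting years);
    * hours per FTE per run = baseline service hours / baseline FTEs.

    Progression hazards default to the balance-equation calibration at the
    default (zero) net inflow, i.e. zero: with an absorbing Palliative phase
    any positive hazard would drain the stationary mix.  Use
    :func:`pdcaresim.oracle.calibrate` to rebalance them for configurations
    with positive net inflow.
    """
    phase_profiles = _default_phase_profiles()
    distribution = PhaseDistribution()
    reporting_years = 3.0
    baseline = reference.ACTIVITY_MEANS["baseline"]

    mean_doctor_rate = sum(
        distribution.share(ph) * phase_profiles[ph].mean_rate("doctor")
        for ph in PHASE_ORDER
    )
    population = round(baseline["doctor_visits"] / (reporting_years * mean_doctor_rate))

    therapy_profiles: dict[Therapy, TherapyProfile] = {}
    for th in THERAPY_ORDER:
        usage = _THERAPY_USAGE[th]
        target = baseline[f"{th.value}_visits"]
        rate = target / (population * usage * reporting_years)
        therapy_profiles[th] = TherapyProfile(th, usage, rate, _TABLE_UNIT_COSTS[th])

    costs = CostSchedule(
        doctor_visit_cost=_TABLE_UNIT_COSTS["doctor"],
        nurse_visit_cost=_TABLE_UNIT_COSTS["nurse"],
        therapy_unit_costs={th: _TABLE_UNIT_COSTS[th] for th in THERAPY_ORDER},
    )
    staffing = StaffingSchedule(
        hours_per_doctor_visit=1.0,
        hours_per_nurse_visit=1.0,
        doctor_hours_per_fte_per_run=baseline["doctor_visits"]
        / reference.BASELINE_DOCTOR_FTE,
        nurse_hours_per_fte_per_run=baseline["nurse_visits"]
        / reference.BASELINE_NURSE_FTE,
    )
    run = RunConfig(prevalent_population=population)
    progression = {ph: 0.0 for ph in PHASE_ORDER}
    return ParameterSet(
        referral_mix=ReferralMix(),
        phase_distribution=distribution,
        phase_profiles=phase_profiles,
        therapy_profiles=therapy_profiles,
        community_referral_probability=1.0,
        cost_schedule=costs,
        staffing=staffing,
        run=run,
        progression=progression,
    )


def background_unit_costs(p: ParameterSet) -> ParameterSet:
    """Alternative cost profile using the rounded national reference-cost
    quotes (physiotherapy 38, occupational therapy 56, SLT 98 GBP/visit)."""
    profiles = dict(p.therapy_profiles)
    for th, cost in _BACKGROUND_UNIT_COSTS.items():
        profiles[th] = replace(profiles[th], unit_cost=cost)
    therapy_costs = {th: prof.unit_cost for th, prof in profiles.items()}
    costs = replace(p.cost_schedule, therapy_unit_costs=therapy_costs)
    return replace(p, therapy_profiles=profiles, cost_schedule=costs)


# ---------------------------------------------------------------------------
# validation


def _check_proportion(out: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(f"{name} = {value} must lie in [0, 1]")


def validate_parameters(p: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff ``p`` is valid).

    Never raises; each entry names the offending field and the constraint.
    """
    out: list[str] = []

    mix = p.referral_mix
    for src in REFERRAL_SOURCES:
        _check_proportion(out, f"referral_mix.{src}", getattr(mix, src))
    if abs(sum(mix.as_tuple()) - 1.0) > _SUM_TOL:
        out.append(
            f"referral_mix proportions sum to {sum(mix.as_tuple())}, must sum to 1"
        )

    dist = p.phase_distribution
    for ph in PHASE_ORDER:
        _check_proportion(out, f"phase_distribution.{ph.value}", dist.share(ph))
    if abs(sum(dist.as_tuple()) - 1.0) > _SUM_TOL:
        out.append(
            f"phase_distribution proportions sum to {sum(dist.as_tuple())}, must sum to 1"
        )

    if set(p.phase_profiles) != set(PHASE_ORDER):
        out.append("phase_profiles must contain exactly the four disease phases")
    for ph, prof in p.phase_profiles.items():
        for role in ("doctor", "nurse"):
            lo, hi = prof.rate_range(role)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                out.append(f"phase_profiles[{ph.value}].{role} range must be finite")
            elif not (0.0 <= lo <= hi):
                out.append(
                    f"phase_profiles[{ph.value}].{role} range ({lo}, {hi}) "
                    "must satisfy 0 <= min <= max"
                )

    if set(p.therapy_profiles) != set(THERAPY_ORDER):
        out.append("therapy_profiles must contain exactly the six therapies")
    for th, tprof in p.therapy_profiles.items():
        _check_proportion(
            out, f"therapy_profiles[{th.value}].usage_probability",
            tprof.usage_probability,
        )
        if tprof.visits_per_year < 0:
            out.append(f"therapy_profiles[{th.value}].visits_per_year must be >= 0")
        if tprof.unit_cost < 0:
            out.append(f"therapy_profiles[{th.value}].unit_cost must be >= 0")

    _check_proportion(out, "community_referral_probability",
                      p.community_referral_probability)

    costs = p.cost_schedule
    for name in ("doctor_visit_cost", "nurse_visit_cost", "emergency_admission_cost"):
        if getattr(costs, name) < 0:
            out.append(f"cost_schedule.{name} must be >= 0")
    for th, c in costs.therapy_unit_costs.items():
        if c < 0:
            out.append(f"cost_schedule.therapy_unit_costs[{th.value}] must be >= 0")
        prof = p.therapy_profiles.get(th)
        if prof is not None and c != prof.unit_cost:
            out.append(
                f"cost_schedule.therapy_unit_costs[{th.value}] = {c} disagrees "
                f"with therapy_profiles[{th.value}].unit_cost = {prof.unit_cost}"
            )

    st = p.staffing
    for name in (
        "hours_per_doctor_visit",
        "hours_per_nurse_visit",
        "doctor_hours_per_fte_per_run",
        "nurse_hours_per_fte_per_run",
    ):
        if getattr(st, name) <= 0:
            out.append(f"staffing.{name} must be strictly positive")

    run = p.run
    if run.warmup_years < 0:
        out.append("run.warmup_years must be >= 0")
    if run.reporting_years <= 0:
        out.append("run.reporting_years must be > 0")
    if run.n_replications < 1:
        out.append("run.n_replications must be >= 1")
    if run.prevalent_population < 0:
        out.append("run.prevalent_population must be >= 0")
    if run.annual_incidence < 0:
        out.append("run.annual_incidence must be >= 0")

    for ph in PHASE_ORDER:
        prob = p.progression.get(ph)
        if prob is None:
            out.append(f"progression missing phase {ph.value}")
        elif not (0.0 <= prob <= 1.0):
            out.append(f"progression[{ph.value}] = {prob} must lie in [0, 1]")
    pal = p.progression.get(Phase.PALLIATIVE)
    if pal not in (None, 0.0):
        out.append("progression[palliative] must be 0 (absorbing phase)")

    if p.consultation_model not in ("poisson", "fixed_interval"):
        out.append(
            f"consultation_model = {p.consultation_model!r} must be "
            "'poisson' or 'fixed_interval'"
        )
    if p.diagnosis_delay_years < 0:
        out.append("diagnosis_delay_years must be >= 0")
    if p.emergency_admission_rate < 0:
        out.append("emergency_admission_rate must be >= 0")

    return out


# ---------------------------------------------------------------------------
# serialization


def to_dict(p: ParameterSet) -> dict[str, Any]:
    """Plain-dict form of a ParameterSet (the on-disk YAML schema)."""
    return {
        "referral_mix": {s: getattr(p.referral_mix, s) for s in REFERRAL_SOURCES},
        "phase_distribution": {
            ph.value: p.phase_distribution.share(ph) for ph in PHASE_ORDER
        },
        "phase_profiles": {
            ph.value: {
                "doctor_visits_per_year": list(prof.doctor_visits_per_year),
                "nurse_visits_per_year": list(prof.nurse_visits_per_year),
            }
            for ph, prof in sorted(p.phase_profiles.items(), key=lambda kv: kv[0].value)
        },
        "therapy_profiles": {
            th.value: {
                "usage_probability": prof.usage_probability,
                "visits_per_year": prof.visits_per_year,
                "unit_cost": prof.unit_cost,
            }
            for th, prof in sorted(p.therapy_profiles.items(), key=lambda kv: kv[0].value)
        },
        "community_referral_probability": p.community_referral_probability,
        "progression": {ph.value: p.progression[ph] for ph in PHASE_ORDER},
        "cost_schedule": {
            "doctor_visit_cost": p.cost_schedule.doctor_visit_cost,
            "nurse_visit_cost": p.cost_schedule.nurse_visit_cost,
            "emergency_admission_cost": p.cost_schedule.emergency_admission_cost,
        },
        "staffing": {
            f.name: getattr(p.staffing, f.name) for f in fields(StaffingSchedule)
        },
        "run": {f.name: getattr(p.run, f.name) for f in fields(RunConfig)},
        "consultation_model": p.consultation_model,
        "diagnosis_delay_years": p.diagnosis_delay_years,
        "emergency_admission_rate": p.emergency_admission_rate,
    }


def from_dict(data: Mapping[str, Any]) -> ParameterSet:
    """Build a ParameterSet from the plain-dict schema (all keys required)."""
    try:
        phase_profiles = {
            Phase(ph): PhaseProfile(
                Phase(ph),
                tuple(float(x) for x in spec["doctor_visits_per_year"]),
                tuple(float(x) for x in spec["nurse_visits_per_year"]),
            )
            for ph, spec in data["phase_profiles"].items()
        }
        therapy_profiles = {
            Therapy(th): TherapyProfile(
                Therapy(th),
                float(spec["usage_probability"]),
                float(spec["visits_per_year"]),
                float(spec["unit_cost"]),
            )
            for th, spec in data["therapy_profiles"].items()
        }
        cost = data["cost_schedule"]
        p = ParameterSet(
            referral_mix=ReferralMix(**{k: float(v) for k, v in data["referral_mix"].items()}),
            phase_distribution=PhaseDistribution(
                **{k: float(v) for k, v in data["phase_distribution"].items()}
            ),
            phase_profiles=phase_profiles,
            therapy_profiles=therapy_profiles,
            community_referral_probability=float(data["community_referral_probability"]),
            cost_schedule=CostSchedule(
                doctor_visit_cost=float(cost["doctor_visit_cost"]),
                nurse_visit_cost=float(cost["nurse_visit_cost"]),
                emergency_admission_cost=float(cost["emergency_admission_cost"]),
                therapy_unit_costs={
                    th: prof.unit_cost for th, prof in therapy_profiles.items()
                },
            ),
            staffing=StaffingSchedule(**{k: float(v) for k, v in data["staffing"].items()}),
            run=RunConfig(
                warmup_years=float(data["run"]["warmup_years"]),
                reporting_years=float(data["run"]["reporting_years"]),
                n_replications=int(data["run"]["n_replications"]),
                master_seed=int(data["run"]["master_seed"]),
                prevalent_population=int(data["run"]["prevalent_population"]),
                annual_incidence=float(data["run"]["annual_incidence"]),
            ),
            progression={Phase(ph): float(v) for ph, v in data["progression"].items()},
            consultation_model=str(data["consultation_model"]),
            diagnosis_delay_years=float(data["diagnosis_delay_years"]),
            emergency_admission_rate=float(data["emergency_admission_rate"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"malformed parameter data: {exc!r}") from exc
    return p


def _merge(defaults: Any, override: Any, path: str) -> Any:
    """Recursively overlay ``override`` on ``defaults``; unknown keys error."""
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ParameterError(f"config key {path or '<root>'} must be a mapping")
        merged = dict(defaults)
        for key, value in override.items():
            sub = f"{path}.{key}" if path else str(key)
            if key not in defaults:
                raise ParameterError(f"unknown config key: {sub}")
            merged[key] = _merge(defaults[key], value, sub)
        return merged
    return override


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a YAML config, filling unspecified fields from the default
    fixture; raises :class:`ParameterError` naming the offending key or
    invariant on any problem."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"config file {path} is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must contain a mapping at top level")
    merged = _merge(to_dict(default_parameters()), raw, "")
    p = from_dict(merged)
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("invalid parameters: " + "; ".join(violations))
    return p


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write ``p`` to YAML; ``load_parameters`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(to_dict(p), sort_keys=False))


def parameter_digest(p: ParameterSet) -> str:
    """Stable SHA-256 digest of the semantic content (for provenance logs)."""
    canonical = json.dumps(to_dict(p), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
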