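"""Turn activity ledgers into the three indicator families.

* Level of activity — visit counts per category, with hospital and
  community totals.
* Resource requirements — service hours (visits x hours/visit) and FTEs
  (hours / hours one full-time contract supplies per reporting window).
  FTEs are requirement-derived, not capacity-constrained servers.
* Treatment costs — exact products of visit counts and per-visit unit
  costs, held as exact arithmetic (integer counts x integer unit costs give
  pound-exact totals).

Costs and hours are computed from the run-end counts rather than accrued
per event; the result is identical and the audit trail simpler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .config import CostSchedule, ParameterSet, StaffingSchedule, Therapy

__all__ = [
    "ActivityLedger",
    "ResourceRequirement",
    "CostBreakdown",
    "tally_activity",
    "resource_requirements",
    "cost_breakdown",
    "all_indicators",
    "INDICATOR_ORDER",
]

#: Canonical indicator order used by reports and exports.
INDICATOR_ORDER: tuple[str, ...] = (
    "doctor_visits",
    "nurse_visits",
    "total_hospital_visits",
    *(f"{th.value}_visits" for th in Therapy),
    "total_community_visits",
    "doctor_hours",
    "nurse_hours",
    "doctor_fte",
    "nurse_fte",
    "total_fte",
    "doctor_cost",
    "nurse_cost",
    "total_hospital_cost",
    *(f"{th.value}_cost" for th in Therapy),
    "total_community_cost",
    "total_cost",
)


@dataclass(frozen=True)
class ActivityLedger:
    """Post-warm-up visit counts for one replication."""

    doctor_visits: int = 0
    nurse_visits: int = 0
    therapy_visits: Mapping[Therapy, int] = field(
        default_factory=lambda: {th: 0 for th in Therapy}
    )

    @property
    def total_hospital_visits(self) -> int:
        return self.doctor_visits + self.nurse_visits

    @property
    def total_community_visits(self) -> int:
        return sum(self.therapy_visits.values())

    def as_dict(self) -> dict[str, int]:
        out = {
            "doctor_visits": self.doctor_visits,
            "nurse_visits": self.nurse_visits,
            "total_hospital_visits": self.total_hospital_visits,
        }
        for th in Therapy:
            out[f"{th.value}_visits"] = self.therapy_visits.get(th, 0)
        out["total_community_visits"] = self.total_community_visits
        return out


@dataclass(frozen=True)
class ResourceRequirement:
    """Service hours and requirement-derived FTEs for one ledger."""

    doctor_hours: float
    nurse_hours: float
    doctor_fte: float
    nurse_fte: float

    @property
    def total_fte(self) -> float:
        return self.doctor_fte + self.nurse_fte

    def as_dict(self) -> dict[str, float]:
        return {
            "doctor_hours": self.doctor_hours,
            "nurse_hours": self.nurse_hours,
            "doctor_fte": self.doctor_fte,
            "nurse_fte": self.nurse_fte,
            "total_fte": self.total_fte,
        }


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category treatment costs (GBP) for one ledger."""

    doctor_cost: float
    nurse_cost: float
    therapy_costs: Mapping[Therapy, float]

    @property
    def total_hospital_cost(self) -> float:
        return self.doctor_cost + self.nurse_cost

    @property
    def total_community_cost(self) -> float:
        return sum(self.therapy_costs.values())

    @property
    def total_cost(self) -> float:
        return self.total_hospital_cost + self.total_community_cost

    def as_dict(self) -> dict[str, float]:
        out = {
            "doctor_cost": self.doctor_cost,
            "nurse_cost": self.nurse_cost,
            "total_hospital_cost": self.total_hospital_cost,
        }
        for th in Therapy:
            out[f"{th.value}_cost"] = self.therapy_costs.get(th, 0)
        out["total_community_cost"] = self.total_community_cost
        out["total_cost"] = self.total_cost
        return out


def tally_activity(events: Iterable, warmup_years: float = 0.0) -> ActivityLedger:
    """Count qualifying events (doctor reviews, nurse visits, therapy
    visits) at or after the warm-up cut, each exactly once.

    Non-activity kinds (arrivals, diagnoses, phase changes) are ignored;
    an unknown kind raises ``ValueError``.
    """
    from .engine import EventKind  # local import to avoid a cycle

    doctor = nurse = 0
    therapy = {th: 0 for th in Therapy}
    for ev in events:
        if ev.kind not in EventKind.ALL:
            raise ValueError(f"unknown event kind: {ev.kind!r}")
        if ev.time < warmup_years:
            continue
        if ev.kind == EventKind.DOCTOR_REVIEW:
            doctor += 1
        elif ev.kind == EventKind.NURSE_VISIT:
            nurse += 1
        elif ev.kind == EventKind.THERAPY_VISIT:
            therapy[Therapy(ev.payload["therapy"])] += 1
    return ActivityLedger(doctor, nurse, therapy)


def resource_requirements(ledger: ActivityLedger,
                          staffing: StaffingSchedule) -> ResourceRequirement:
    """Hours and FTEs implied by a ledger under a staffing schedule."""
    if staffing.doctor_hours_per_fte_per_run <= 0 or staffing.nurse_hours_per_fte_per_run <= 0:
        raise ValueError("hours per FTE per run must be strictly positive")
    doctor_hours = ledger.doctor_visits * staffing.hours_per_doctor_visit
    nurse_hours = ledger.nurse_visits * staffing.hours_per_nurse_visit
    return ResourceRequirement(
        doctor_hours=doctor_hours,
        nurse_hours=nurse_hours,
        doctor_fte=doctor_hours / staffing.doctor_hours_per_fte_per_run,
        nurse_fte=nurse_hours / staffing.nurse_hours_per_fte_per_run,
    )


def cost_breakdown(ledger: ActivityLedger, costs: CostSchedule) -> CostBreakdown:
    """Category costs = visits x unit cost; totals are exact sums.

    Raises ``KeyError`` if the ledger contains a therapy with no unit cost.
    """
    therapy_costs = {}
    for th, visits in ledger.therapy_visits.items():
        if visits and th not in costs.therapy_unit_costs:
            raise KeyError(f"no unit cost configured for therapy {th.value!r}")
        therapy_costs[th] = visits * costs.therapy_unit_costs.get(th, 0)
    return CostBreakdown(
        doctor_cost=ledger.doctor_visits * costs.doctor_visit_cost,
        nurse_cost=ledger.nurse_visits * costs.nurse_visit_cost,
        therapy_costs=therapy_costs,
    )


def all_indicators(ledger: ActivityLedger, p: ParameterSet) -> dict[str, float]:
    """The full indicator vector (activity, resources, costs) for one
    ledger under the parameter set's schedules, in canonical order."""
    values = ledger.as_dict()
    values.update(resource_requirements(ledger, p.staffing).as_dict())
    values.update(cost_breakdown(ledger, p.cost_schedule).as_dict())
    return {name: values[name] for name in INDICATOR_ORDER}
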