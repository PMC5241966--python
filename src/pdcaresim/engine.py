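"""Seeded discrete-event kernel: event calendar, clock, replication runner.

The kernel is deliberately generic — an ordered event calendar with a
monotone clock and FIFO tie-breaking — with the disease/care logic supplied
by :mod:`pdcaresim.pathway`.  Reproducibility discipline:

* every replication gets an integer seed derived from the experiment's
  master seed via :func:`replication_seed`;
* within a replication, each stochastic purpose (arrivals, patient
  attributes, therapy assignment, scenario selection, consultation gaps,
  progression draws) has its own named NumPy generator spawned from that
  seed, so that scenarios sharing a master seed share patient-level draws
  (common random numbers for paired scenario contrasts).

Identical (parameters, scenario, seed) triples yield identical ledgers.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import numpy as np

from .accounting import ActivityLedger
from .config import ParameterSet, Phase, Therapy, validate_parameters

__all__ = [
    "Event",
    "EventKind",
    "EventCalendar",
    "ReplicationResult",
    "SchedulingError",
    "STREAM_NAMES",
    "replication_seed",
    "replication_streams",
    "run_replication",
    "run_experiment",
]


class SchedulingError(RuntimeError):
    """An event was scheduled in the past — a pathway-logic bug."""


class EventKind:
    ARRIVAL = "arrival"
    DIAGNOSIS = "diagnosis"
    DOCTOR_REVIEW = "doctor_review"
    NURSE_VISIT = "nurse_visit"
    THERAPY_VISIT = "therapy_visit"
    PHASE_CHANGE = "phase_change"

    ALL = frozenset(
        {ARRIVAL, DIAGNOSIS, DOCTOR_REVIEW, NURSE_VISIT, THERAPY_VISIT, PHASE_CHANGE}
    )


@dataclass(frozen=True)
class Event:
    """A timestamped occurrence for one patient.

    ``time`` is in simulation years, 0 being the start of the warm-up
    period.  ``payload`` carries kind-specific attributes (the therapy name
    for therapy visits, the referral source for arrivals, a generation
    counter for cancellable nurse schedules).
    """

    time: float
    kind: str
    patient_id: int | None = None
    payload: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time >= 0.0):
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")


class EventCalendar:
    """Time-ordered event queue with FIFO tie-breaking.

    Events dequeue in non-decreasing time order; equal-time events dequeue
    in insertion order.  Scheduling before the current clock raises
    :class:`SchedulingError`.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, Event]] = []
        self._counter = itertools.count()
        self._clock = 0.0

    def __len__(self) -> int:
        return len(self._heap)

    @property
    def clock(self) -> float:
        """Time of the most recently dequeued event (0 before any)."""
        return self._clock

    def schedule(self, event: Event) -> None:
        if event.time < self._clock:
            raise SchedulingError(
                f"cannot schedule {event.kind} at t={event.time} "
                f"before current clock t={self._clock}"
            )
        heapq.heappush(self._heap, (event.time, next(self._counter), event))

    def next_event(self) -> Event | None:
        if not self._heap:
            return None
        time, _, event = heapq.heappop(self._heap)
        self._clock = time
        return event

    def __iter__(self) -> Iterator[Event]:
        while (event := self.next_event()) is not None:
            yield event


@dataclass(frozen=True)
class ReplicationResult:
    """Outcome of one seeded replication: the post-warm-up activity ledger
    and the end-of-run phase census (for occupancy diagnostics)."""

    replication_index: int
    seed: int
    ledger: ActivityLedger
    final_phase_counts: Mapping["Phase", int] | None = None


#: Named random streams, one per stochastic purpose.
STREAM_NAMES: tuple[str, ...] = (
    "arrivals",
    "attributes",
    "therapy",
    "scenario",
    "consult_doctor",
    "consult_nurse",
    "consult_therapy",
    "progression",
)

_SEED_MASK = 0x7FFFFFFF  # replication seeds stay below 2**31


def replication_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replication seed: the first word of
    ``SeedSequence([master_seed, index])``, masked to 31 bits."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]) & _SEED_MASK


def replication_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per named stochastic purpose."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(STREAM_NAMES, children)
    }


def run_replication(p: ParameterSet, scenario: "ScenarioSpec", seed: int,
                    replication_index: int = 0) -> ReplicationResult:
    """Run one seeded replication and return its post-warm-up ledger.

    Processes the event calendar from t=0 to the end of the horizon
    (warm-up + reporting years); only events at or after the warm-up cut
    are tallied.  A pure function of ``(p, scenario, seed)``.
    """
    from . import pathway  # deferred: pathway imports Event from this module

    violations = validate_parameters(p)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    scenario.validate()

    streams = replication_streams(seed)
    horizon = p.run.horizon_years
    warmup = p.run.warmup_years
    sim = pathway.PathwayState(p, scenario, streams)
    calendar = EventCalendar()

    doctor_visits = 0
    nurse_visits = 0
    therapy_visits = {th: 0 for th in Therapy}

    for patient in pathway.initialize_population(p, streams, scenario=scenario):
        sim.register(patient)
        for ev in sim.initial_events(patient, horizon):
            calendar.schedule(ev)
    for ev in pathway.generate_arrivals(p, streams, horizon=horizon):
        calendar.schedule(ev)

    for event in calendar:
        t = event.time
        if t >= horizon:
            continue
        counted = t >= warmup
        kind = event.kind
        if kind == EventKind.DOCTOR_REVIEW:
            if counted:
                doctor_visits += 1
            for ev in sim.on_doctor_review(event, horizon):
                calendar.schedule(ev)
        elif kind == EventKind.NURSE_VISIT:
            follow = sim.on_nurse_visit(event, horizon)
            if follow is None:
                continue  # stale schedule superseded by a phase change
            if counted:
                nurse_visits += 1
            for ev in follow:
                calendar.schedule(ev)
        elif kind == EventKind.THERAPY_VISIT:
            if counted:
                therapy_visits[Therapy(event.payload["therapy"])] += 1
            for ev in sim.on_therapy_visit(event, horizon):
                calendar.schedule(ev)
        elif kind == EventKind.ARRIVAL:
            for ev in sim.on_arrival(event, horizon):
                calendar.schedule(ev)
        elif kind in (EventKind.DIAGNOSIS, EventKind.PHASE_CHANGE):
            pass  # bookkeeping markers; no activity tallied
        else:
            raise ValueError(f"unknown event kind: {kind!r}")

    ledger = ActivityLedger(
        doctor_visits=doctor_visits,
        nurse_visits=nurse_visits,
        therapy_visits=therapy_visits,
    )
    phase_counts = {ph: 0 for ph in Phase}
    for patient in sim.patients.values():
        phase_counts[patient.phase] += 1
    return ReplicationResult(replication_index=replication_index, seed=seed,
                             ledger=ledger, final_phase_counts=phase_counts)


def run_experiment(p: ParameterSet, scenario: "ScenarioSpec",
                   n_replications: int | None = None,
                   master_seed: int | None = None) -> list[ReplicationResult]:
    """Run the replication design of ``p.run`` (overridable) and return one
    :class:`ReplicationResult` per replication.

    Replication seeds derive deterministically from the master seed, so two
    experiments with the same master seed are identical, and experiments on
    different scenarios share per-replication randomness.
    """
    n = p.run.n_replications if n_replications is None else n_replications
    master = p.run.master_seed if master_seed is None else master_seed
    return [
        run_replication(p, scenario, replication_seed(master, i), replication_index=i)
        for i in range(n)
    ]
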