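"""Published activity and validation figures for the study NHS Trust.

These numbers are model *inputs*: the baseline column calibrates the default
parameter fixture (prevalent population and community-therapy visit rates),
the scenario columns define the default scenario multipliers, and the
real-world column drives the validation harness.  Costs and staffing figures
are not stored — they are exact products of these activity levels and the
unit-cost / staffing schedules, and are recomputed by :mod:`pdcaresim.accounting`.
"""

from __future__ import annotations

from types import MappingProxyType

#: Mean visit counts per 3-year reporting window, by scenario.  The baseline
#: column is the calibration target for the default fixture; scenario columns
#: are the observed effect of shifting 10/20/40/50% of patients to
#: community-based management in the study Trust's evaluation.
ACTIVITY_MEANS = MappingProxyType({
    "baseline": MappingProxyType({
        "doctor_visits": 8225,
        "nurse_visits": 10357,
        "physiotherapy_visits": 3554,
        "slt_visits": 3357,
        "psychiatry_visits": 1776,
        "occupational_visits": 2335,
        "palliative_care_visits": 454,
        "dietician_visits": 434,
    }),
    "scenario_1": MappingProxyType({
        "doctor_visits": 7494,
        "nurse_visits": 9854,
        "physiotherapy_visits": 3700,
        "slt_visits": 3494,
        "psychiatry_visits": 1850,
        "occupational_visits": 2420,
        "palliative_care_visits": 477,
        "dietician_visits": 456,
    }),
    "scenario_2": MappingProxyType({
        "doctor_visits": 7158,
        "nurse_visits": 9553,
        "physiotherapy_visits": 4036,
        "slt_visits": 3811,
        "psychiatry_visits": 2019,
        "occupational_visits": 2640,
        "palliative_care_visits": 519,
        "dietician_visits": 496,
    }),
    "scenario_3": MappingProxyType({
        "doctor_visits": 6537,
        "nurse_visits": 8831,
        "physiotherapy_visits": 4708,
        "slt_visits": 4447,
        "psychiatry_visits": 2355,
        "occupational_visits": 3079,
        "palliative_care_visits": 606,
        "dietician_visits": 579,
    }),
    "scenario_4": MappingProxyType({
        "doctor_visits": 5873,
        "nurse_visits": 8016,
        "physiotherapy_visits": 6755,
        "slt_visits": 6379,
        "psychiatry_visits": 3378,
        "occupational_visits": 4150,
        "palliative_care_visits": 731,
        "dietician_visits": 818,
    }),
})

#: 95% replication intervals for the baseline scenario (empirical percentiles
#: across 100 replications of the study Trust model).
BASELINE_INTERVALS = MappingProxyType({
    "doctor_visits": (7732, 8801),
    "nurse_visits": (10046, 10771),
    "physiotherapy_visits": (3341, 3767),
    "slt_visits": (3256, 3592),
    "psychiatry_visits": (1723, 1847),
    "occupational_visits": (2265, 2428),
    "palliative_care_visits": (440, 481),
    "dietician_visits": (421, 451),
    "total_hospital_visits": (17778, 19572),
    "total_community_visits": (11446, 12566),
})

#: Real-world (Trust records) values used by the validation harness.
VALIDATION_OBSERVED = MappingProxyType({
    "doctor_visits": 8061,
    "nurse_visits": 10875,
    "doctor_hours": 8061,
    "nurse_hours": 10875,
    "doctor_fte": 1.04,
    "nurse_fte": 3.57,
})

#: Baseline staffing requirement (FTEs) implied by the activity levels; used
#: to derive the hours-per-FTE capacity constants of the default fixture.
BASELINE_DOCTOR_FTE = 1.07
BASELINE_NURSE_FTE = 3.4


def scenario_multipliers(scenario: str) -> dict[str, float]:
    """Per-category activity multipliers of ``scenario`` relative to baseline.

    Returned keys are the eight visit categories with the ``_visits`` suffix
    stripped (``doctor``, ``nurse``, ``physiotherapy``, ...).
    """
    base = ACTIVITY_MEANS["baseline"]
    scen = ACTIVITY_MEANS[scenario]
    return {k.removesuffix("_visits"): scen[k] / base[k] for k in base}
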