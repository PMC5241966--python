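# Methods

## Model structure

The simulator is an individual-level discrete event model of one NHS
Trust's Parkinson's disease caseload. Entities are patients; events are
referrals, diagnoses, doctor reviews, nurse visits, community-therapy
visits, and phase changes, processed on a continuous-time event calendar
(years; no time-step discretization, since every schedule is rate-based).
Ties on the calendar dequeue first-in-first-out, which makes a replication
a pure function of (parameters, scenario, seed).

Each patient carries a disease phase (Diagnosis → Maintenance → Complex →
Palliative), a referral source, personal doctor and nurse visit rates
drawn uniformly from the phase profile's closed range, and a set of
community therapies assigned independently by usage probability.
Consultations and therapy visits are Poisson processes at the personal
rates. Rigid fixed-interval appointments are available as a config switch
(`consultation_model: fixed_interval`, first appointment at a uniform
phase offset so the warm-up reaches the stationary renewal state), but the
Poisson default is preferred: the source frequencies are ranges ("2 to 3
times a year"), Poisson scheduling makes every analytic expectation exact,
and it reproduces the spread of the published replication intervals.

Phase progression is evaluated only at doctor reviews: with the configured
per-phase hazard the patient advances one phase and redraws their
consultation rates from the new profile (any pending nurse schedule is
invalidated via a generation counter and restarted, which is exact under
memoryless gaps). Palliative is absorbing. Progression never moves a
patient backwards.

## Default parameters (the calibrated Trust fixture)

| parameter | default | units | basis |
|---|---|---|---|
| referral mix (GP, A&E, outpatient, other) | .75, .15, .05, .05 | proportion | Trust records |
| phase mix (D, M, C, P) | .10, .60, .25, .05 | proportion | Trust records |
| doctor visit ranges | [1,1], [2,3], [3,4], [3,4] | visits/yr | Trust records |
| nurse visit ranges | [2,4] ×3, [12,12] | visits/yr | Trust records (monthly palliative care plan) |
| therapy usage (physio, SLT, OT, psych, diet, pall) | .45, .425, .35, .225, .075, .075 | probability | senior-clinician consensus |
| therapy visit rates | 2.544, 2.544, 2.542, 2.149, 1.950, 1.864 | visits/yr | calibrated (below) |
| unit costs doctor / nurse | 220 / 150 | GBP/visit | cost ÷ activity tables, exact integer divisions |
| unit costs physio / SLT / OT / others | 38 / 96 / 58 / 50 | GBP/visit | cost ÷ activity tables |
| hours per visit | 1.0 / 1.0 | h | activity and service-hour tables are numerically identical |
| hours per FTE per run, doctor / nurse | 7686.92 / 3046.18 | h | baseline hours ÷ baseline FTEs (1.07 / 3.4) |
| run design | 1y warm-up + 3y reporting, 100 reps | — | published run design |
| prevalent population | 1035 | patients | calibrated (below) |
| net annual inflow | 0 | patients/yr | steady caseload (below) |
| progression hazards | 0, 0, 0 | per review | balance calibration at zero inflow (below) |
| community referral probability | 1.0 | probability | uptake already encoded in usage probabilities |

Two documented alternatives ship alongside the defaults:
`guideline_phase_profiles()` (the national-guideline frequencies 2, 4, 5,
6 visits/year, both roles) and `background_unit_costs()` (the rounded
national reference-cost quotes, SLT £98 and occupational therapy £56).
The table-implied values are the defaults because the published results
tables are exact products of activity and those unit costs, while the
rounded quotes are not internally consistent with them. An emergency
admission cost (£2,133) exists as an inert config hook; admissions are
not simulated (rate fixed at 0, outside the scope of the activity tables).

### Calibration identities

Every baseline expectation is linear in its free parameter, so
calibration is a sequence of exact one-dimensional solves in a fixed
order (population, then therapy rates, then progression hazards), each
verified to 0.5% — a degenerate, deterministic case of monotone
root-bracketing:

* mean doctor rate under the stationary mix: 0.1·1 + 0.6·2.5 + 0.25·3.5 +
  0.05·3.5 = 2.65 visits/patient-year, so the caseload is
  8225 / (3 × 2.65) ≈ 1034.6, rounded to 1035 whole patients;
* each therapy rate = baseline therapy visits / (1035 × usage probability
  × 3 years), e.g. physiotherapy 3554 / (1035 × 0.45 × 3) ≈ 2.544/yr;
* progression hazards solve the flow-balance equations of the review-time
  transition chain: inflow enters Diagnosis, each interior phase passes
  the same flow, so hazard_i = inflow / (N × share_i × doctor-rate_i).

### The steady-caseload reading

The default fixture treats the Trust caseload as stationary:
`annual_incidence` is the *net* inflow (incident diagnoses minus deaths
and transfers, which are not modelled separately) and defaults to 0. This
is the only reading consistent with the calibration identity above — any
positive net inflow would inflate the visit expectations away from the
baseline targets — and with the Trust observation that the phase mix is
essentially constant. Because Palliative is absorbing, the balance
equations at zero inflow give identically zero progression hazards: the
shipped fixture models a caseload in equilibrium, where phase churn has no
net effect on any expectation. The arrival and progression machinery is
fully active for any configuration with positive inflow (the calibrator
rebalances the hazards, and the test suite exercises such configurations),
but users studying demand growth should set `annual_incidence` and
recalibrate explicitly.

## Scenarios

The four shipped scenarios ("10/20/40/50% more patients shifted to
community services") are multiplier-mode: each patient's per-category
visit rates are scaled by the ratio of the published scenario mean to the
published baseline mean for that category. This is deliberate: the verbal
shift rules under-determine the published per-category effects (most
visibly the sharply non-linear community-visit growth under the largest
shift), so the package reproduces the published effects exactly in
expectation rather than guessing a mechanism. The mechanistic mode
(select each patient with the shift probability; halve hospital rates,
double therapy rates by default) is provided for prospective what-if
analysis and for the monotonicity property (hospital activity
non-increasing in the shift fraction), but its defaults are not claimed
to reproduce the published scenario columns.

## Analytic oracle

Expected phase occupancy obeys a linear ODE: the expected flux out of
phase *i* is occupancy × mean review rate × hazard, and referrals enter
Diagnosis at the net inflow rate. The occupancy integral over the
reporting window is computed to machine precision with one augmented
matrix exponential; expected visits are the integral dotted with the
per-phase rates, and therapy expectations are uptake × rate ×
patient-years. Mechanistic scenarios are handled exactly as a two-group
mixture (managed / unmanaged subpopulations).

With the default (zero) hazards the oracle is exact for the engine. With
positive hazards it neglects the within-patient correlation between the
sampled review rate and progression speed (faster-reviewed patients
progress sooner); the error is second order in the hazards and immaterial
at the balanced hazards used in tests (≤ 0.05 per review).

## Randomness and reproducibility

Replication seeds derive from the master seed as the first word of
`SeedSequence([master_seed, index])` (31-bit). Within a replication each
stochastic purpose — arrivals, patient attributes, therapy assignment,
scenario selection, the three consultation gap streams, progression —
has its own generator spawned from the replication seed. Attribute and
selection draws therefore align across scenarios sharing a master seed
(common random numbers), which tightens paired scenario contrasts.

## Output analysis

Replication summaries report the arithmetic mean with an empirical 95%
interval (2.5th/97.5th percentiles, linear interpolation: position
1 + q(n−1)); published replication intervals are asymmetric about the
mean, which a symmetric t-interval cannot produce, though a Student-t
option exists. Percent changes are computed from unrounded means and
rounded only at render time (whole percents by default, one decimal on
request; FTEs render at 2 d.p.). Costs are exact integer arithmetic
wherever counts and unit costs are integers.

## Problem sizes in the test suite

The suite runs the full published design where it matters: the baseline
and all four shipped scenarios at 100 replications of the 1035-patient
fixture (a few minutes in total on one CPU). Distributional unit checks
use 10,000-draw samples with 3σ binomial/Poisson bands; the stationarity
property uses 60 replications of a positive-inflow configuration so the
Monte Carlo error of the mean phase share (~0.1 points) is small against
its ±2-point band; the common-random-numbers monotonicity check uses 25
replications per shift fraction.

## What the generator does and does not emulate

The synthetic caseload reproduces the study Trust's marginal structure —
referral mix, phase mix, consultation-rate ranges, therapy uptake and
volumes — and the replication design. It does not model patient age, sex,
comorbidity, psychology or socio-economic status, appointment
non-attendance, inpatient/emergency episodes, surgery, mortality, waiting
times or capacity constraints (FTEs are requirement-derived, not
constrained servers; the published tables show no congestion effects).
Passing tests therefore demonstrate internal consistency with the
published activity/cost/staffing structure of one large Trust, not
transferability to Trusts with different pathways or service coverage.

## Known limitations

* Scenario effects beyond the published four rest on the multiplier
  ratios; the mechanistic mode is a stylised rule, not an estimate.
* The published "~32% FTE reduction under the largest shift" headline is
  inconsistent with the published FTE table itself (1 − 3.36/4.47 ≈ 25%);
  the package reproduces the table, and its comparison machinery yields
  the table-implied percentages.
* Zero default progression hazards mean phase churn is only exercised in
  positive-inflow configurations; a Trust wanting within-cohort
  progression with a stationary mix would need an explicit exit process
  (e.g. palliative mortality), which is out of scope here.
* Nurse-visit expectations derive from the stated phase profiles
  (≈ 3.45/patient-year), slightly above the published baseline nurse
  count; the published interval covers the model's expectation, and no
  nurse-side free parameter exists to recalibrate without overriding the
  stated ranges.
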