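# Methods

This note documents the model implemented in `adjuvant_cea`: its
structure, the numerical and design choices that were genuinely open,
what the synthetic-data generator does and does not emulate, and the
known limitations.

## Survival model

Surgery-only relapse-free survival (RFS) and overall survival (OS) are
two-piece Weibull models with cumulative hazard H(t) = λ·t^γ on each
segment, t in weeks. Both pieces are anchored at the time origin: the
second piece's (λ, γ) describe H(t) = λ·t^γ evaluated from t = 0, not
from the breakpoint. This origin-anchored reading is adopted because it
reproduces all twelve published 3- and 5-year model-outcome survival
probabilities to within 0.12 percentage points (see
`tests/test_acceptance.py::TestSurvivalCalibration`); a
breakpoint-anchored reading does not. At the breakpoint itself the
earlier piece applies (left-closed intervals); the published rounded
parameters leave a ≤2% relative step in H at internal breakpoints,
which the constructor tolerates with a warning above that threshold
rather than an error.

Treatment curves apply hazard ratios under proportional hazards,
S_hr(t) = S_base(t)^hr. RFS uses the S-1 trial's RFS HR and the XELOX
trial's DFS HR (DFS standing in for RFS); both trials share surgery
alone as the common comparator, which is what licenses the indirect
comparison.

Curve fitting (`fit_piecewise_weibull`) regresses ln(−ln S) on ln t per
segment by unweighted least squares — slope γ, intercept ln λ — and
reports r² on that transformed scale. Points with S ∈ {0, 1} carry no
information after the transform and are dropped with a warning.

## Background mortality

Extrapolated beyond trial follow-up, a disease model can imply
implausibly low mortality at old ages. A life table (1-year age bands,
CSV `age_years,qx`) supplies a weekly background hazard
h_b = −ln(1−q_x)/52 at the cohort's attained age. Modes:

* `additive` (default): h_b is added to each curve's weekly hazard
  increment from `from_week` onward. The default start is week 260,
  the 5-year trial follow-up horizon, so the observed period is left
  untouched and natural-cause mortality accrues only in the
  extrapolated tail.
* `max`: the weekly hazard is floored at h_b (nearly inert during
  follow-up for this disease, where model hazards exceed population
  hazards).
* `off`: no adjustment.

The additive-beyond-follow-up default was selected by comparing both
candidate readings against the published base case: it reproduces the
reported discounted QALYs (model 6.30 / 7.99 / 8.17 vs published
6.2 / 7.8 / 8.1), totals within ~6%, and all three reported one-way
threshold crossings (upper RFS hazard ratio, upper oxaliplatin cost,
and upper discount rate each push the XELOX-vs-surgery ICER past
$6,100), whereas the hazard-floor variant yields systematically higher
QALYs and misses two of those crossings. The adjustment is applied to
both RFS and OS globally, i.e. the recurrence state inherits the same
blended OS curve.

The bundled life table (`data/life_table_synthetic.csv`) is synthetic:
a Gompertz–Makeham hazard μ(x) = A + B·e^{Cx} with A = 5·10⁻⁴,
B = 4.14·10⁻⁵, C = 0.092, closed at age 100, calibrated to a period
life expectancy at birth of 76 years — representative of the general
population the cohort is drawn from without redistributing any official
table. Any table with the same CSV schema can be supplied in the
configuration.

## Cohort engine

Weekly cycles from age 59.5 to age 100 (2,106 cycles; "lifetime" in
practice, with residual cohort occupancy at the horizon reported so the
truncation error is visible — under 0.3% of the cohort is still alive
at age 100 in the base case). Occupancy is partitioned from the curves;
where the independently extrapolated RFS curve eventually crosses OS
(around week 900 for surgery), recurrence occupancy is clamped at zero
with a warning and RFS is capped by OS.

Cycle values are taken at cycle start: cycle k spans [week k, week
k+1) and is valued at the state occupancy at week k; a half-cycle
(trapezoid) option exists but is off by default — at 1-week cycles the
difference is below 0.1%. Discounting uses (1+r)^(−k/52) with r = 0.03
per year.

Deaths in cycle k split into background deaths from RFS — occupancy ×
life-table weekly death probability — and the remainder, attributed to
cancer ("excess" attribution, the default; `all` attributes every death
to cancer). Cancer deaths trigger the one-time end-of-life cost; new
recurrences are the RFS decrement net of background deaths from RFS.

## Costing

Doses scale with body surface area (Mosteller, √(kg·cm/3600) = 1.72 m²
for the 65 kg / 1.64 m reference patient).

* Oxaliplatin (130 mg/m² per 3-week cycle, intravenous): every opened
  50 mg vial is billed, per the discard rule — 223.6 mg → 5 vials.
* Oral agents use dispensing-band (nearest-unit) rounding by default:
  S-1 at 40 mg/m² twice daily → 68.8 mg → 60 mg (3 × 20 mg) per
  administration, matching the trial's actual BSA-banded dosing tiers;
  capecitabine 1000 mg/m² twice daily → 1720 mg → 1500 mg (3 × 500 mg
  tablets). The vial-discard rule textually covers opened vials, not
  tablets; nearest banding also reproduces the published
  relapse-free-state cost for S-1, which strict round-up overshoots by
  roughly a third. Per-drug `rounding: up` remains available in the
  configuration.
* Schedules: XELOX, eight 3-week cycles (24 weeks), with per-cycle
  adverse-event and hospitalization costs; S-1, eight 6-week cycles
  (4 weeks on / 2 off, 48 weeks — "repeated for 1 year" read as eight
  whole cycles), with per-cycle monitoring-test and adverse-event
  costs. Cycle costs are spread uniformly over the cycle's weeks and
  weighted by RFS occupancy.
* Follow-up: one $56.5 follow-up unit per 12 weeks while in RFS after
  treatment ends (the cadence is not published; 12 weeks is a standard
  surveillance interval in the first years and the knob is part of the
  one-way sensitivity analysis, range 6–26 weeks).
* Recurrence: entrants accrue the 86.5%/13.5% salvage/supportive mix
  (salvage $2,334.6 per 3-week cycle for seven cycles ⇒ a 21-week
  salvage phase; supportive $115.2 per 3-week cycle) and thereafter the
  supportive rate. Implementation: the finite salvage-phase *excess*
  over supportive care is convolved with the new-recurrence inflow,
  while the open-ended supportive rate is carried by living recurrence
  occupancy — a literal open-ended convolution would keep billing
  patients after death. This slightly overstates salvage cost for
  entrants who die within 21 weeks of relapse (a small minority) and is
  the conservative direction.
* End-of-life: $1,460.3 once per attributed cancer death, discounted at
  the cycle of death. All amounts are 2013 USD as published; no
  inflation or currency conversion.

## Comparison

Strategies are ranked by cost; strict dominance (weakly costlier and
less effective, strictly on one axis) and extended dominance (iterative
removal of frontier points whose sequential ICER exceeds the next
one's — equivalent to the lower convex hull of the cost-effectiveness
plane, property-tested against a brute-force chord oracle) are flagged.
Net health benefit ΔE − ΔC/WTP and net monetary benefit ΔE·WTP − ΔC
use WTP anchors of $6,100 and $18,300 per QALY.

## Sensitivity analysis

One-way: every cost with a published range, both utilities, all four
hazard ratios (at their 95% CI bounds), the discount rate (0–6%, the
standard guideline span, as no range is published) and the follow-up
cadence are set to each bound in turn, everything else at base; bars
are sorted by |ΔNHB| at WTP $6,100. Cost and utility parameters are
varied independently (joint variation is not specified in the source
analysis).

Probabilistic: second-order parameter sampling around the exact cohort
engine — costs lognormal (μ = ln median, σ = (ln high − ln low)/(2·1.96),
reading the published ranges as central 95% intervals, the conventional
interpretation), utilities beta (moment-matched to mean = base,
sd = range/(2·1.96)), hazard ratios normal on the log scale from their
95% CIs, RFS and OS HRs drawn independently (no correlation is
published; a correlation knob defaults to 0). One seeded generator;
draws occur in sorted parameter-name order so results are independent
of configuration insertion order. The published analysis additionally
resampled 1,000 patients per iteration; that first-order layer is
available (`first_order_patients`) but off by default, since
acceptability curves reflect parameter uncertainty and the cohort
evaluation is exact. CEAC ties split equally among maximizers, so
columns sum to one exactly.

At 1,000 iterations the XELOX strategy is cost-effective at the $6,100
threshold in roughly two-thirds of draws (0.66–0.71 across seeds),
matching the published headline.

## Synthetic data

`synthetic.py` generates the patient-level inputs the aggregate
parameters summarize: event/censoring times by inverse-CDF sampling
(vectorized bisection on H(t) = −ln u to 10⁻¹⁰ weeks, a uniform code
path for any number of pieces) with administrative censoring only
(matching trial follow-up structure; no random dropout), and skewed
billing-record costs (lognormal, same parameterization as the PSA).
The generator emulates the *shape* of trial data — proportional-hazards
arms, piecewise hazards, right-censoring — but not covariate structure,
non-proportional hazards, dose reductions, or informative censoring;
passing recovery tests therefore demonstrates internal consistency of
the pipeline, not robustness to those real-data features.

Recovery surfaces (all in the test suite): noiseless fits are exact to
6 significant digits; 100,000 simulated, Kaplan–Meier-estimated
patients recover the generating (λ, γ) within 5%; the full
simulate → KM → fit → trace → accrue round trip reproduces the
generating model's discounted QALYs within 2%; and cohort occupancies
match a 100,000-patient microsimulation within three Monte-Carlo
standard errors at 1, 3, 5 and 10 years. The microsimulation oracle
couples each patient's RFS and OS times through a single uniform
(comonotone inversion), which preserves both marginals and the
recurrence occupancy identity; per-cycle coupled stepping cannot do so
once the extrapolated OS hazard overtakes the RFS hazard (≈week 210).

Problem sizes used in the shipped tests — 100,000 patients for
recovery/microsimulation checks, 1,000 PSA iterations, 1,000 random
strategy sets for the frontier oracle — keep the whole suite around
ten seconds while leaving Monte-Carlo error well inside every asserted
tolerance.

## Known limitations

* The published base case is not bit-reproducible from its reported
  inputs alone:
  the costing calendar (follow-up cadence, within-cycle timing) is
  under-specified, and the source's own QALY and cost figures are
  internally inconsistent (its summary-table QALY row disagrees with
  its abstract; its discussion quotes a different XELOX total than its
  table). This model reproduces the abstract QALYs to ±0.2, totals to
  ~6%, and the S-1 ICER to ~1%; the XELOX-vs-surgery ICER lands at
  $4,480 vs the published $3,502 — both on the same side of every
  decision threshold.
* Proportional hazards is assumed for both endpoints over the whole
  horizon; no spline/cure-model extrapolation alternatives.
* The indirect comparison inherits the cross-trial comparability
  assumption of its two source trials.
* Independent RFS/OS extrapolation forces clamping where the curves
  cross (~17 years out for surgery); occupancy there is dominated by
  background mortality, so the effect on discounted totals is small.
* Utilities are single-state constants; no adverse-event disutilities
  or time-varying quality of life.
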