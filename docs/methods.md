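# Methods

This note documents the analytic conventions, the synthetic-data model,
and the design decisions behind `rxtraj`, in the order the pipeline runs.

## Day arithmetic and intervals

All dates are integer day offsets from an arbitrary per-dataset epoch;
an optional calendar-date ingestion mode is deliberately absent from the
core so that every rule is exactly testable. Intervals are closed on
both ends: a prescription with `start == end` lasts one day, and a
14-day course spans `end − start + 1 = 14`. "12 months" is a 365-day
window (`[t, t+364]`), and 52 weeks is 364 days. The gap between two
prescriptions of the same drug is `next.start − previous.end`, so a gap
of exactly 60 days does **not** merge under the strict `< 60` rule,
while 59 does.

## Cohort selection

The index date is the earliest diagnosis bearing an index code
(ICD-9 301.83 / ICD-10 F60.3). The eligibility criteria are evaluated
in a fixed order (age, baseline treatment, follow-up, lifetime
exclusion, current exclusion) purely for labelling: eligibility itself
is a conjunction and order-independent, which the tests assert. Choices
that the underlying study description leaves open:

* **"Current" diagnosis** is undefined in the source setting; here a
  code recorded within `current_window_days` (default 365) before the
  index date, or up to 14 days after it, counts as current. It is
  configurable on `CohortSpec`.
* **"≥ 52 weeks of visit data"** is implemented as last visit ≥ 364
  days after index. A visit-density requirement would be an alternative
  reading; density is not modelled.
* **Baseline treatment** requires a merged psychotropic episode that
  *intersects* the ±14-day window and has *total* length ≥ 14 days —
  course length, not in-window days. A 14-day course that merely
  touches the window therefore qualifies.
* **Psychotropic scope** is the packaged drug→class map: any mapped
  drug counts, unmapped drugs do not.
* **Age** is completed years at index (floor of days/365.25).

## Episodes

Merging is transitive within (patient, drug): chains of records with
neighbouring gaps < 60 days collapse to one episode regardless of total
span. The ≥ 14-day minimum-duration (PRN) filter is applied **after**
merging, so two 10-day records 30 days apart survive as one 54-day
episode. Same-drug records at different doses are assumed to be
pre-normalised to one drug name; dose is not modelled.

Each drug maps to exactly one class. Where a drug is pharmacologically
ambiguous (lamotrigine, valproate and gabapentin act as
anticonvulsants), the packaged map follows the clinical-usage
convention of BPD prescribing studies and classes them as mood
stabilisers; trazodone is classed as an antidepressant and hydroxyzine
as an anxiolytic. The map is a two-column CSV that can be replaced
wholesale by the user. Unmapped drugs are dropped with a logged count by
default (`unmapped="other"` retains them).

## Polypharmacy

The unit of counting is the *drug*, not the class. The concurrency
timeline is a sweep over episode endpoints; because same-drug episodes
are disjoint after merging, active-episode count equals distinct-drug
count on every day. Polypharmacy in a window requires some drug pair
whose co-active days *inside the window* total ≥ 14 (overlap days
accumulate across episode pairs of the same two drugs). This makes a
stop-one-start-another switch with < 14 days of overlap a
non-polypharmacy event by construction.

Checkpoint windows are not prescribed by the source setting; the
package evaluates checkpoint *t* on `[t − 35, t + 35]` days
(baseline on the ±14-day index window), and the denominator at each
checkpoint is the *qualifying* patients — those with ≥ 1 active episode
in the window — which reproduces the characteristic declining-n pattern
of such tables. Both choices are parameters of
`checkpoint_windows`/`checkpoint_table`. Drug-pair combination counts
require the pair to overlap *each other* in-window (not merely each
overlap the window), and a patient may contribute to several pairs.

## Trajectories

Journey states are maximal intervals of constant active-class set,
including the empty set ("none"); per patient they tile the analysis
window exactly. State labels are sorted class names joined with `+`,
giving deterministic tie-breaks. Treatment changes are detected at drug
level — a within-class switch is a change even though the class-set
state does not move — matching the distinction between class-level
Sankey flows and drug-level switching.

For the post-baseline journey the initial state is the class set active
on the index day; cohort inclusion should guarantee it is non-empty, and
`journey_to_first_change(..., require_baseline=True)` raises if not (an
eligible patient whose baseline episode ends inside the ±14-day window
before index would trigger this, so the orchestrated pipeline runs with
`require_baseline=False`, anchoring such patients at their first
in-window initiation). For the pre-baseline window the initial state is
the first non-empty state and never-treated patients are dropped,
which is why the pre-baseline sub-cohort is smaller than the cohort.

Continuation for a class is 100 × (window days covered by ≥ 1 episode
of the class) / (window length), over the 12-month post-index window by
default; an alternative first-to-last-prescription window can be passed
explicitly. Aggregates use the sample SD (`ddof=1`; a single patient
reports SD 0.0) and the normal-theory CI below.

## Statistics kernel

Proportions use Wald intervals, `pct ± 1.959964·100·√(p(1−p)/n)`
clipped to [0, 100]; means use `mean ± 1.959964·sd/√n`. These two forms
were selected because they exactly reproduce the printed intervals of
the tables this pipeline re-derives at 1-decimal rounding (a Wilson
interval does not). Display rounding is half-up at one decimal —
57.95 → 58.0 — applied to the unrounded bound; unrounded values are kept
on the result objects. No inferential testing or multiplicity
correction is performed anywhere: the pipeline is descriptive.

## Synthetic-data model

The generator is a first-class, tested module, not a fixture. Per
patient it draws: demographics (truncated-normal age, mean 35.2, SD
12.8, minimum 12 years; categorical gender/race/ethnicity matching the
emulated cohort's margins), independent Bernoulli comorbidities
(including exclusion-list diagnoses so the attrition cascade is
exercised), an index diagnosis, visits with exponential inter-visit
gaps (mean 21 days) from 365 days before index to 560 days after (15%
of patients "drop out" 100–350 days post-index and fail follow-up),
CGI-S scores centred on the moderately-ill band, and symptom labels.

Prescribing is a three-phase process chosen to be the **simplest one
with closed-form baseline margins**:

* *Baseline*: each class initiates independently with its configured
  probability (defaults: antidepressant 0.80, SGA 0.42, anxiolytic
  0.36, mood stabiliser 0.32, anticonvulsant 0.20, hypnotic/sedative
  0.16, analgesic 0.11, stimulant 0.09, SUD drug 0.05, FGA 0.03), one
  weighted drug per class, start uniform in the 14 days up to index,
  duration ≥ 90 days plus a gamma(2, 90) draw. The defaults imply a
  baseline antidepressant rate of 0.80 and a conditional (≥ 1-drug)
  multi-drug rate of 0.831 — the margins of the cohort the generator
  emulates. `expected_baseline_class_rate` and
  `expected_baseline_multidrug_rate` return these values exactly,
  marginalising over comorbidity boosts by enumeration.
* *Pre-baseline*: optional earlier courses (half the baseline
  initiation probability) that end ≥ 75 days before index.
* *Post-baseline*: per-class daily initiation hazard (default 0.001)
  starting 15 days after index, gamma-distributed durations.

Same-drug re-prescriptions follow each course with probability 0.3
after a uniform 10–90-day gap, deliberately straddling the 60-day merge
threshold; PRN courses (Poisson, mean 1.2/patient) last 1–13 days and
are removed by the minimum-duration filter. The three phase boundaries
(baseline durations ≥ 90 days and starts at or before index;
pre-baseline courses ending ≥ 75 days before index; post-baseline
initiations ≥ 15 days after) are what keep the measured baseline
polypharmacy equal to the closed-form class-count margin: every pair of
baseline drugs overlaps ≥ 15 days inside the ±14-day window, and
nothing else enters it for ≥ 14 days.

Comorbidity-conditional prescribing is a multiplicative boost on the
class probability (defaults: MDD→antidepressant ×1.1,
anxiety→anxiolytic ×1.2, ADHD→stimulant ×3, SUD→SUD-drug ×4, capped at
0.98); parameter-recovery checks disable the boosts so configured and
measured probabilities coincide exactly.

Randomness uses one root `SeedSequence` split into one child stream per
output table, so adding a table never perturbs the draws of another;
identical seeds give byte-identical tables.

**What the generator does not emulate** — and what passing tests
therefore do not establish about real data: calendar structure
(weekday/holiday visit patterns), dose and route, informative dropout
(dropout is independent of prescribing), correlated comorbidities,
diagnosis-code noise, within-class drug correlations, and any treatment
*response* process (the rising-then-plateauing polypharmacy trajectory
of real cohorts is only loosely matched). Episode-duration and
visit-cadence distributions are stated assumptions, not observed facts.

## Numerical choices and degenerate inputs

Empty inputs yield empty, schema-correct outputs rather than errors
(`n_patients=0`, empty cohorts, checkpoints with zero qualifying
patients emit `n=0` rows with missing proportions). Ties in journey
ranking break lexicographically by label. Malformed rows on ingestion
(non-integer days, `end < start`, CGI-S outside 1–7) are dropped and
itemised in a validation report; a missing required table is fatal.
Sweep-line structures use `end + 1` sentinel breakpoints so closed
intervals never produce off-by-one days; every interval algorithm is
fuzz-tested against an independent day-grid oracle that paints days
into sets and re-derives the result by enumeration.

## Problem sizes

The test suite exercises 500 seeded oracle-equivalence cases on small
record sets, parameter recovery at n = 5000 patients, and smaller
cohorts (n = 60–300) elsewhere; the acceptance script generates
n = 4000 patients. These sizes give binomial standard errors of ~0.5%
on the recovered margins, comfortably separating the configured values
from their 3-SE acceptance bands.
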