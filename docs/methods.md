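# Methods

This note documents the models, conventions and numerical choices behind
`periwalk`, and what the synthetic-data validation does and does not show.

## Minute normalization and window maxima

Distance records are apportioned assuming **constant speed within a
record**: a record of `v` meters over `[s, e)` contributes
`v · |bin ∩ [s,e)| / (e − s)` to each minute bin it overlaps. The export
format gives no sub-record speed information, so the uniform rule is the
maximum-entropy choice; it also makes the apportionment exactly
invertible for bout-structured data, which the synthetic generator
exploits. Degenerate cases: a zero-duration record credits its whole
value to the bin containing its start instant; a record crossing midnight
contributes to each civil day only its overlap with that day. Per
patient-day, bin sums conserve apportioned distance to ~1e−12 relative
(floating-point only).

Window maxima are taken over **minute-aligned** contiguous windows fully
inside the civil day (`n − w + 1` windows; never across midnight — each
day is scored independently), computed in O(n) from prefix sums. The
minute-aligned convention follows from normalizing first: the "timeline"
is the per-minute vector, and windows slide over it. Arbitrary-phase
continuous windows would be ≥ the minute-aligned value but are not what a
per-minute normalized dataset supports.

Civil days follow the phone's local wall clock. Exports carry fixed UTC
offsets per record, not a timezone database, so day bounds are inferred
from the offsets of the records touching the day: if the offset changes
within a day (daylight-saving transition) the day has 1380 or 1500 minute
bins and the window count adapts. A day with no records defaults to 1440
bins (its metrics are zero regardless).

## Daily steps and active time

Steps are summed per civil day; a record spanning midnight is split
across days **in proportion to temporal overlap** and the day total is
rounded half-up (a deterministic integer rule). Assignment by record
start date is available as an option, since date-aggregation of step
records admits either reading.

Active time is the **union** of the day's distance-record spans clipped
to the day, in hours. Summing raw durations would double-count
overlapping records and could exceed 24 h; the union keeps
`active_time_h ≤ 24` provable (25 on a fall-back day).

Days with zero or very low recorded activity are kept as true zeros —
no exclusion, no imputation, no wear-time correction. Daily metrics
therefore conflate "did not walk" with "did not carry the phone"; this is
a property of the measurement, preserved deliberately.

## Perioperative intervals

The four intervals are half-open day-offset ranges against the surgery
date: baseline [−183, −14), final two preoperative weeks [−14, 0), early
postoperative [0, 14), late postoperative [14, 42). Choices that were
genuinely open and how they were fixed:

* **Baseline excludes the final two preoperative weeks**, so the four
  intervals partition [−183, 42) and paired contrasts compare disjoint
  periods. A sensitivity variant (`IntervalSpec.with_full_baseline`)
  makes baseline the full [−183, 0); overlapping days then resolve to the
  narrower interval.
* **Surgery day belongs to early postoperative** (offset 0 is "after
  surgery").
* Calendar words map to whole days: "2 weeks" = 14 days, "2–6 weeks" =
  28 days, "6 months" = 183 days.

Per patient × interval, daily values reduce to mean, median, **sample SD
(n−1)** — days are treated as a sample of the patient's period — and
`CV% = 100·SD/mean`, defined only when mean > 0 and n ≥ 2 (flagged
otherwise). The per-patient value entering the paired tests is the
interval **mean** of daily values (median available via config); the mean
is additive and consistent with the CV's denominator.

## Test routing and multiplicity

For each metric and interval pair, paired differences d = b − a over
complete pairs (patients missing either side are dropped pairwise;
n ≥ 3 required) are routed by Shapiro–Wilk at α = 0.05: normal-looking
→ two-sided paired *t*; otherwise two-sided Wilcoxon signed-rank with
zero differences discarded (classic convention; Pratt handling was the
alternative), mid-rank ties, exact null distribution when the nonzero
count is ≤ 25 without ties, else the normal approximation with continuity
correction. All-zero differences short-circuit to a degenerate result
with p = 1; constant nonzero differences (Shapiro–Wilk undefined) route
to the signed-rank test.

The Simes–Hochberg step-up adjustment is applied within the family of the
**six interval pairs of one metric** (per-metric families; a global
family across all metrics is available via config). The step-up
recursion — adj(m) = p(m), adj(i) = min(adj(i+1), (m−i+1)·p(i)), capped
at 1 — is implemented directly and cross-checked in the tests against a
brute-force evaluation of the definition and against an independent
library implementation.

Pooled Pearson correlations over patient-days use pairwise-complete
observations and carry no clustering or mixed-effects correction: with
~200 repeated days per patient they are descriptive, not inferential, and
are labeled as such.

## Synthetic cohort model

Each patient-day draws `K ~ Poisson(bouts_per_day)` walking bouts.
Bouts get log-normal durations (minutes, clipped to [2, 180]), uniform
non-overlapping start times between 06:00 and 23:00 (rejection-sampled;
infeasible placements reduce the bout count), and one constant gait speed
per bout from a zero-truncated normal. Each bout emits a distance record
and a step record (`steps = round(cadence · distance)`, cadence 1.35
steps/m). Phone carriage is per-bout Bernoulli thinning
(`carry_probability`, default 0.85), so zero-activity days occur
naturally. Timestamps are whole seconds at a fixed +01:00 offset.

Ground truth is computed analytically from the retained bouts by the same
minute-apportionment convention, which makes the end-to-end identity
testable: parse → normalize → window-max on the written XML reproduces
ground truth to ≤ 1e−6 relative (observed ~1e−14), steps exactly.

Default phase parameters (rates, durations, speed means/SDs per phase)
are calibrated so the cohort's median per-patient 1-min maxima follow a
perioperative trajectory of roughly 98 → 82 → 82 → 105 m across
baseline → final two preoperative weeks → early → late postoperative,
with daily steps around 3–6 k and active time 0.8–1.3 h/day. These are
generator defaults, never test oracles.

What the generator does **not** emulate, hence what passing tests do not
show about real exports: within-bout speed fluctuation and fatigue (the
constant-speed model makes the 6-min maximum nearly 6× the 1-min maximum
and their pooled correlation ≈ 0.99, higher than free-living data would
give); GPS/terrain distance error; multiple overlapping source devices;
daylight-saving transitions (generated data use one fixed offset, though
the parser and binning handle offset changes); and any patient-reported
outcomes.

A second, summary-level simulator (`simulate_interval_cohort`) draws
per-patient interval values directly as
`μ_{metric,interval} + b_patient + ε` with
`b ~ N(0, between_sd²)`, `ε ~ N(0, paired_diff_sd²/2)` (so any two
intervals' paired difference has SD `paired_diff_sd`). It exists for
operating-characteristic studies of the comparison suite — null
family-wise error and planted-effect power — where thousands of cohorts
are needed and bout-level detail is irrelevant.

## Problem sizes and numerical conventions

* End-to-end validation runs the full 41-patient cohort (225 days each,
  9 225 patient-days), matching the statistical size the analysis is
  meant for.
* Operating characteristics: Shapiro routing calibration uses 1 000
  replicates at n = 41; null family-wise error uses 500 summary-level
  cohorts (bound 0.05 + 2·MC-SE); planted-effect power (+23 m on the
  preop → late contrast, paired-difference SD 30 m, n = 41) uses 100
  replicate cohorts.
* Sliding-window equivalence against brute-force enumeration is asserted
  as exact float equality; the random timelines are drawn on a dyadic
  grid (multiples of 1/64) so every partial sum is exactly representable
  and different summation orders cannot disagree.
* All simulation randomness flows through `numpy.random.Generator`
  seeded explicitly; cohort generation spawns per-patient child seeds
  from one `SeedSequence`, so outputs are reproducible and independent of
  patient count ordering effects.

## Known limitations

* Distance is taken at face value from the phone; no device-level error
  model or cross-device deduplication (overlapping distinct sources only
  trigger a warning).
* Minute-aligned windows slightly underestimate an arbitrary-phase
  continuous window maximum.
* CV is undefined for zero-mean periods (fully inactive patients drop out
  of stability summaries, which is reported via the `cv_defined` flag).
* Pooled correlations ignore within-patient clustering by design and must
  not be read as population effect sizes.
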