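# Methods

## Scope and units

`cgmrisk` quantifies *when* in the 24-hour day hypoglycemia occurs in
cohorts monitored by 5-minute CGM. The counting unit throughout is the
**epoch**: one nominal reporting interval (default 5 minutes). A reading
at local clock time *t* represents the half-open interval
[*t*, *t* + epoch); monitored time is `epoch × n_readings`, so sensor gaps
contribute nothing and are never interpolated. Glucose is held internally
in mmol/L at 2-decimal precision (mg/dL inputs divided by 18.016, the
conversion consistent with the conventional 3.5 mmol/L ↔ 63 mg/dL pairing).
Timestamps are naive wall-clock times at minute resolution: hour-of-day
binning is a wall-clock concept, so no timezone or DST arithmetic is
performed, and duplicate timestamps keep the first occurrence with a
logged count.

Device censoring: Dexcom-style sensors report only down to 2.2 mmol/L
("Low") and up to a ceiling ("High"). Low readings are imputed at the
floor and flagged `clipped="low"` — this preserves minute accounting while
recording that the true value is censored; an event whose minimum sits at
the floor carries `nadir_clipped=True`. Exclusion intervals (half-open
`[start, end)`) delete readings, e.g. in-hospital controlled fasts, and can
only reduce monitored time.

## Episode detection

A hypoglycemia event is a **maximal run of consecutive readings strictly
below the threshold** (default 3.5 mmol/L; a reading exactly at the
threshold is not hypoglycemic). Consecutiveness additionally requires the
inter-reading gap ≤ `max_gap_minutes` (default 7.5 = 1.5 epochs): a longer
gap splits the run, because unobserved time must not be counted as
hypoglycemia. Event duration is `n_epochs × epoch`, never `end − start`,
which would silently bridge gaps. The minimum event is a single epoch
(5 minutes). "Prolonged" events last strictly more than 30 minutes, i.e.
≥ 35 minutes on a 5-minute grid. All SDs are sample SDs (n − 1); an SD
over a single observation is reported as 0 with a warning so summary
tables stay total-safe.

Detection is verified against a brute-force run-enumeration oracle on
randomized traces, and satisfies minute conservation (Σ durations =
epoch × number of below-threshold readings), maximality, and monotonicity
of total hypoglycemic minutes in the threshold (event *counts* are not
monotone — lowering the threshold can split runs).

## Hourly profiles and clock windows

Each reading credits its whole epoch to the hour bin of its own timestamp
(an epoch starting 03:55 belongs to hour 3 — no splitting; the 5-minute
granularity does not justify sub-epoch attribution). Event start hours use
the first below-threshold reading. Clock windows are half-open
`[start:00, end:00)` and may wrap midnight; the early-hours window
03:00–07:00 has width 4 h and expected hypo-minute share 100·4/24 = 16.7%.
Cohort profiles pool minutes across patients (the published convention);
per-group profiles are recomputed from member traces so partitions always
reconcile to cohort totals.

Reported percentages use half-up rounding: 1 decimal for prose-style
rates, 2 decimals for table-style shares. Published subgroup tables the
package reproduces appear to *truncate* some values (e.g. a share of
38.095 printed as 38.09); the package does not imitate truncation.

## Statistical tests

- **Pearson chi-square (2×2, df = 1)** from the closed form
  `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, optional Yates correction
  (off by default — minute-count cells are huge and the correction is
  immaterial). Degenerate margins are refused by naming the margin.
- **Mann–Whitney U** from midranks; exact enumeration of the permutation
  null when min(n₁, n₂) ≤ 8, tie-corrected normal approximation otherwise;
  identical constant samples yield p = 1 with a note. Two-sided
  throughout; no multiple-testing correction is applied.

Both are authored in the package (scipy supplies only distribution
functions and `rankdata`) and are cross-checked in the test suite against
`scipy.stats.chi2_contingency` / `scipy.stats.mannwhitneyu` as independent
references.

**Counting-unit caveat.** The minute-count chi-square treats every
5-minute epoch as independent, but epochs inside one event are perfectly
dependent. Under the generator's own uniform-hazard null its design effect
is roughly E[D²]/(E[D]·epoch) ≈ 25 for the configured duration
distribution, and its empirical type-I error is far above the nominal 5%.
It is retained as the descriptive convention for pooled minutes; for
calibrated inference the package provides `event_start_chi2`, a
goodness-of-fit chi-square on event-start counts inside vs outside the
window with expected counts proportional to monitored minutes — events are
the approximately independent units, and this test holds its nominal size
in the simulation study. Neither test models between-patient correlation
of pooled minutes; that limitation is documented, not fixed.

**Tendency labels** summarise a window qualitatively from the risk ratio
(rr = inside % / outside %): rr ≥ 3 → "++", ≥ 2 → "+", ≥ 1.5 → "−",
≥ 1 → "−−"; rr < 1.2 with a hypo-minute share within 5 points of the
expected share → "evenly distributed"; rr < 1 otherwise marks a protected
window. The banding is a reporting convention of this package.

**Subgroup conventions.** Age splits at 10 months with the *older* group
defined as ≥ 10 months (this reproduces the reference cohort's 16/7
split, which includes a patient aged exactly 10 months). Mutation status
groups "not done" with "negative" — the reference cohort's subgroup minute
totals only reconcile to its overall totals under that grouping, i.e.
untested patients were counted as having no known mutation. Medication is
"on" iff any treatment is listed.

## Synthetic cohort generator

A two-state semi-Markov process per patient on the epoch grid:

- **Normoglycemia**: stationary AR(1), mean 5.5 mmol/L, SD 0.8, lag-1
  correlation ρ = 0.9, clipped below at threshold + 0.3 so baseline noise
  never creates events.
- **Onset**: at each normoglycemic epoch an event starts with probability
  `baseline_onset_prob × frailty × multiplier(hour)`, where the multiplier
  (default 2.5) applies inside the configured window (default 03:00–07:00).
  The epoch immediately after an event is forced normoglycemic so planted
  events never merge.
- **Events**: duration lognormal, moment-matched to mean 35 / SD 57
  minutes and discretised to whole epochs (min 1); within-event glucose is
  a V-shaped dip from just below the threshold to a nadir drawn from a
  Normal(3.1, 0.37) truncated below at the 2.2 sensor floor and capped
  just below the threshold (realised mean ≈ 3.07). The V-shape is the
  simplest form consistent with a defined nadir; no physiological realism
  is claimed.
- **Heterogeneity and missingness**: per-patient frailty is
  lognormal(σ = 0.8), normalised to mean 1 — this reproduces the strong
  positive skew of per-patient event counts (SD ≈ mean ≈ 9.5 at the
  default onset probability of 0.004/epoch over 4–10 days of monitoring).
  Epochs are then dropped i.i.d. with probability 0.02 and values below
  the floor are clipped and flagged. Burst missingness, meals, insulin and
  device noise spectra are out of scope.

Per-patient streams spawn from the master `SeedSequence`, so a config +
seed pair reproduces the cohort bit-for-bit, including the written CSVs.
Cohort metadata (age mixture, mutation, medication, sex, location) is
drawn from fixed plausible frequencies purely so subgroup machinery can be
exercised; it does not influence the glucose process.

What the generator does *not* emulate: postprandial risk spikes, sleep
structure, autocorrelated dropout, sensor error vs plasma glucose.
Passing recovery tests therefore demonstrates correctness of the
*pipeline arithmetic and inference calibration*, not fidelity of any
particular clinical cohort.

## Parameter recovery and calibration

`recovery_check` runs the full detection + profiling pipeline over a
simulated cohort and reports:

- detected vs true event counts and hypoglycemic minutes (with dropout 0
  these agree exactly — every planted event survives as one maximal run);
- the **onset-hazard ratio estimate**: (event starts per non-hypoglycemic
  monitored minute inside the window) / (same outside). This targets the
  configured multiplier directly; the descriptive minutes-based risk ratio
  is attenuated toward 1 by events spilling across window edges (≈ 2.0
  observed at a configured 2.5 with 35-minute mean durations) and is
  reported alongside. The onset estimator itself is mildly attenuated
  (a few percent) by dropout-induced run splitting, the post-event
  refractory epoch, and frailty-exposure weighting; its patient-level
  bootstrap percentile interval covers the configured value in the
  simulation study.
- p-values of both windowed chi-square variants. Under a uniform hazard
  the event-start test rejects at ≈ the nominal 5% across replicate
  cohorts; the minute-count test does not (see above).

Problem sizes used in the shipped calibration checks — a 120–250-patient
null cohort for the window-share convergence, 200 replicate 8-patient
cohorts for the type-I study, a 40–150-patient cohort for hazard-ratio
recovery — were chosen as the smallest sizes at which Monte-Carlo error is
comfortably below the tolerances being checked.

## Known limitations

- Pooled-minute inference ignores within-event and within-patient
  dependence (documented above; the event-start test mitigates the former
  only).
- Hour attribution is whole-epoch; an epoch straddling an hour boundary is
  credited entirely to its start hour.
- "Low" readings are imputed at the floor: statistics involving nadirs are
  upper bounds on severity when `nadir_clipped` is set.
- The generator's within-event V-shape and frailty form are conventions,
  isolated behind `SimulationConfig` so alternatives can be swapped in.
- No warm-up/calibration trimming is applied automatically on day 1;
  exclusion intervals are the mechanism for any such deletion.
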