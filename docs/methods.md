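# Methods

This note documents the models, algorithms and parameter choices behind
`commpart`: what each stage assumes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Measurement model

The pipeline treats a participant-week as three time-aligned streams in
naive local time (the protocol is single-timezone; a config field records
the assumed UTC offset for documentation only):

1. **GPS fixes** at a nominal 5-s epoch, with dropout.  Device exports are
   cleaned by removing "title lines" — header text the logger re-emits
   after signal interruption, recognised as any data line whose timestamp
   field does not parse — trimming to the monitoring window, and
   collapsing duplicate timestamps to the first occurrence (a fixed,
   logged policy chosen for determinism).
2. **Accelerometer counts** per epoch, aggregated to 60-s windows aligned
   to local midnight.  Day boundaries are local midnight throughout.
3. **Diary entries** giving time, activity, venue category, social
   interactions, and sleep windows.

### Data completeness

GPS completeness is audited against the expected cell count
`days × 86,400 / epoch` (120,960 cells for 7 days at 5 s);
`hours_lost = (expected − observed) × epoch / 3600`.  Inclusion gates:
GPS ≥ 480 recorded min/day on ≥ 5 of 7 days; accelerometer ≥ 4 valid days
(≥ 8 h recorded waking time) with at least one weekend day; diary
returned.  A participant enters the cohort statistics only if all three
hold, and the run report lists every exclusion with its reason.

### Intensity classification

Counts per 60-s epoch are classified with wrist cut points light 283,
moderate 605, vigorous 1697; sedentary is waking time below the light
threshold (no separate sedentary cut point exists in this scheme).  Two
interpretive decisions are fixed and configurable:

* **Epoch adjustment.** For epochs other than 60 s the thresholds scale
  linearly by `epoch_s / 60`.  Linear scaling is the simplest defensible
  reading of "adjusted for sampling frequency and epochs"; no published
  formula pins it down, so `CutPoints` takes arbitrary values and a
  reference epoch.
* **Boundaries.** A count exactly at a threshold takes the *higher* class.

Sleep is taken from diary windows only (midpoint-in-window masking,
overlaps merged, idempotent).  Visual inspection of the activity trace —
the other half of how sleep is identified in practice — is a human step
outside algorithmic scope.  Non-wear, if flagged in the diary, is masked
like sleep; no non-wear detection algorithm is included because the
emulated protocol had continuous wear.

### Mobility

The home anchor is the centroid of the densest nocturnal (00:00–06:00)
spatial cluster on a ~50 m grid, refined by the mean of member fixes; ties
break to the southwest-most cell, logged.  Distances use the haversine
formula on a spherical Earth (R = 6,371,000 m), amply accurate at city
scale.

A trip opens when ≥ 2 consecutive fixes fall outside the home radius and
closes when ≥ 2 consecutive fixes return inside (return time = first
inside fix).  Gaps ≤ `bridge_gap_min` inside an episode are carried
through; a longer gap that starts away from home and resumes inside closes
the loop at the last out-of-home fix.  Episodes shorter than
`min_trip_min` are discarded.  Visits are maximal runs of fixes within
`dwell_radius_m` of their running centroid lasting ≥ `min_dwell_min`; each
centroid takes the category of the containing geofence (nearest centre if
several contain it; exact ties break by the category listing order,
residential first), snapping to a fence edge within `max_snap_m`,
otherwise `unknown`.  A visit-less loop whose maximum displacement stays
within `neighbourhood_radius_m` of home is categorised local
walk/greenspace — a neighbourhood walk is itself the visited "location".
A multi-stop outing counts as one trip with several visits.

None of these thresholds is canonical; the defaults are declared
stand-ins, echoed into every run report:

| parameter | default | rationale |
| --- | --- | --- |
| home radius | 100 m | consumer-GPS urban accuracy envelope |
| min trip duration | 5 min | suppresses boundary jitter excursions |
| gap bridge | 10 min | mirrors the diary-matching tolerance |
| dwell radius | 50 m | separates stops from slow travel |
| min dwell | 5 min | a purposeful stop, not a traffic halt |
| snap tolerance | 100 m | one home-radius of positional slack |
| neighbourhood radius | 1,000 m | "close to home" walking range |

### Fusion and diary comparison

Every classified epoch receives exactly one context — home, travel, a
visit category, or `unknown` where a GPS gap's two ends disagree about the
surrounding context.  Diary trips (out-of-home, non-sleep entries) match
GPS trips greedily in chronological order, each taking the earliest
unmatched GPS trip whose departure lies within `tolerance_min` (default
10 min); a property test checks the greedy pair count against brute-force
optimal assignment on small instances.  Category agreement is recorded
separately from the temporal match.  Activities performed on the home
property (e.g. gardening) count as in-home because the diary says so, not
the GPS.  Social interactions are self-reported per entry and tallied
in-home / out-of-home / per venue.

### Statistics

* `describe` chooses mean/SD vs median/IQR by skewness and kurtosis Z
  scores (bias-corrected sample moments over their normal-theory standard
  errors; |Z| ≤ 1.96 for both ⇒ normal).  Constant vectors are flagged
  degenerate; n < 3 yields descriptives only.
* Spearman correlations use average ranks for ties.  P-values use the
  t approximation `t = ρ√((n−2)/(1−ρ²))`; for n ≤ 10 the exact permutation
  distribution is enumerated instead (vectorised over a cached table of
  all n! orderings).  Significance is flagged at α = 0.01 — the convention
  adopted for the many simultaneous correlations, deliberately *not* a
  Bonferroni correction — and at 0.05.  A zero-variance input yields an
  undefined (NaN) ρ, reported as such.
* Paired self-report vs GPS comparisons use the paired t-test on
  differences d = self − GPS, with Bland–Altman bias = mean(d) and limits
  of agreement bias ± 1.96 SD(d) computed on the same differences.  When
  SD(d) = 0 the degenerate convention t = 0, p = 1 applies (all-zero d is
  perfect agreement; constant non-zero d has no within-pair variability
  to test), and the result is flagged.

All statistics are invariant to participant ordering, and the Spearman
matrix and paired t are each cross-checked in the test suite against
independent oracles (rank-then-Pearson; the closed form).

## The synthetic cohort

The generator is the package's test bed and reference workload.  It
simulates a flat synthetic town on real coordinates near (−35.0, 138.6):
circular geofences for the seven venue categories with centres ≥ 300 m
apart (so categorisation is unambiguous), and home sites on a 300-m grid
kept ≥ 450 m from every fence centre.  Monitoring starts on a Monday so
days 6–7 are the weekend.

Per participant, for `days` days:

* **Trips.** Weekly trip counts ~ Normal(median 15, σ from the IQR
  9.25–18.75), rounded and clipped to [0, 35]; allocated across days by a
  capped uniform multinomial (the within-week day allocation is a free
  modelling choice — nothing pins it down — and is therefore a profile
  concern, not a finding).  Venue categories are drawn from weights
  proportional to weekly visit means (commercial most frequent);
  schedules sit on a whole-minute grid between ~09:00 and 21:45.  Local
  walk/greenspace trips walk (1.4 m/s) to the nearest park fence; all
  other trips drive (8 m/s) straight lines between home and a stop point
  inside the destination fence.  A profile switch (`two_stop_prob`,
  default 0) chains a second distinct stop; the default keeps diary
  location reports commensurable with GPS visit counts, while the
  multi-visit code path is exercised in tests.
* **Sleep.** One nocturnal window per night starting within 30 min of
  midnight, duration ~ Normal(480, 58) min clipped to [360, 600].
  Placing the window at the start of the calendar day keeps each night
  inside the monitoring span without changing any downstream tally.
* **Intensity classes** are assigned per minute: sleep; walking trips
  moderate (first/last two minutes light); driving sedentary; dwell time
  light; then at-home MVPA minutes are added to meet a participant-level
  daily target whose mean is `mvpa_min_per_day` minus the expected
  walk-trip contribution (68 min per walk trip, the measured mean under
  the default town), so the cohort median lands on target while walk
  visits and MVPA remain coupled.  MVPA is never placed within 2 min of a
  trip boundary, which makes the fused out-of-home MVPA tally *exactly*
  equal to ground truth rather than equal up to boundary-epoch jitter.
  Surplus sedentary minutes are converted to light to approach the
  sedentary target; because that rebalancing is one-sided, realised
  sedentary time averages ~640 min/day against the 659 nominal — a known,
  documented bias of ~3%.
* **Counts.** Each 5-s epoch draws from a lognormal truncated to its
  class's count band scaled by `epoch_s/60` (σ = 0.5, μ at the band's
  geometric midpoint).  Sub-minute draws therefore sum into the correct
  60-s band, so classification recovers the minute classes exactly at
  both epoch lengths — the recovery invariant the test suite leans on.
* **Signal loss** per participant ~ Exponential(mean 9.3 h), removed as
  epoch-aligned contiguous blocks of ≤ 6 h (so dropout alone cannot fail
  a daily validity gate), with a device-header line written at each
  resume point for the cleaner to find.
* **Diary.** One entry per trip with start/end jittered ±`jitter_min`
  (default 5 min, inside the 10-min matching tolerance), plus
  Poisson(1.3/week) phantom short trips concentrated on commercial and
  recreational venues — the emulated over-reporting bias — plus in-home
  activities and nightly sleep entries.  Social interactions per visit are
  Poisson draws with venue-specific means (residential 1.25, recreational
  1.25, commercial 0.95; zero elsewhere), putting weekly out-of-home
  interactions near 11.5 with recreational and commercial modal.
* **Covariates.** age ~ N(74, 5); HRQOL utility ~ N(0.84, 0.08) clipped to
  [0.2, 1]; loneliness ~ round N(1.4, 1.4) on 0–6; sleep quality ~ round
  N(5.41, 3) on 0–21.  They are deliberately uncoupled from participation,
  matching the null associations the cohort statistics should report.

Everything is deterministic given the profile seed (per-participant
substreams), and identical profiles produce byte-identical outputs.

### What the generator does not emulate

Straight-line constant-speed travel (no road network), no GPS multipath or
urban-canyon error structure beyond 5-m isotropic jitter, no device clock
drift between streams, sleep from the diary channel only, no non-wear, no
item-level questionnaire responses, and independence between covariates
and behaviour.  Passing tests therefore demonstrate that the *pipeline*
recovers what its input model encodes — trip structure, categories,
intensity composition, reporting bias — not that it is robust to every
pathology of field GPS data.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of 6–200 participants
over 7 days (≈ 121 k GPS fixes and 121 k accelerometer epochs per
participant), sizes chosen so the full suite completes in about a minute
while medians and correlations are stable.  Classification and trip
detection are vectorised; visit clustering loops per trip over a few
hundred fixes.  Floating-point comparisons at class boundaries are exact
(`>=` on scaled thresholds); the truncated-lognormal count bands shrink
their upper edge by 0.1% so sub-minute sums cannot graze the next
threshold.  All randomness flows from `numpy.random.default_rng` seeds;
exact-permutation p-values enumerate at most 10! orderings via a cached
int8 table.

## Known limitations

* Trip-detection thresholds are stand-ins; on real data they would need
  sensitivity analysis, and home-radius choice interacts with walking
  departures (a pedestrian takes ~70 s to clear 100 m, so detected
  departures lag schedule departures by up to a minute).
* The diary–GPS mean difference under default dropout exceeds the pure
  over-report rate (phantoms plus trips hidden by gaps) — on real data the
  two causes are confounded exactly the same way.
* The Spearman couplings built into the generator are stronger than
  real-world effect sizes at the same n; they are structural-recovery
  probes, not effect-size claims.
* Multi-visit trips inflate per-venue GPS counts relative to one-entry-
  per-trip diaries; the default profile avoids this by emitting
  single-destination loops.
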