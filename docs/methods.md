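# Methods

This note documents the statistical content of `clawbench`: the KPI
definitions and their conventions, the weighted-kappa reliability gate, the
validation cascade, the percentile benchmarking rules, and — in most detail —
what the synthetic-data generator does and does not emulate, since every
quantitative claim the test suite makes is a claim about data from that
generator.

## Domain model

Claw lesions are coded with a vocabulary shipped as a versioned plain-text
table (`clawbench/data/lesion_vocabulary.csv`): the harmonized
claw-lesion catalogue (thin sole, ulcers, white line disease, horn fissures,
heel horn erosion, …), the six digital-dermatitis stages M0–M4.1 (M0 is
healthy skin, not a lesion), the DD-associated claw horn lesions
(non-healing ulcer/white-line variants), and an explicit no-lesion code
(`NL`) so that lesion-free trimmings are representable.  Every lesion code
maps to exactly one of the 13 benchmark groups or to `other`; the catalogue
is deliberately wider than the 13 groups.

Two classification predicates drive the KPIs:

* **alarm** — the always-painful subset: all ulcers and toe necroses, white
  line abscesses (WLA = white line disease of severity ≥ 2), coronet/bulb
  swellings with deep digital sepsis, interdigital phlegmon, penetrating
  infected horn fissures (a distinct code, `HF-P`, since plain fissures are
  not reliably painful), the acute M2 stage of DD, and all DD-associated
  claw horn lesions.  Chronic DD stages (M1, M3, M4, M4.1) are not alarm.
* **severity-sensitive** — sole haemorrhage, double sole, white line
  disease and heel horn erosion: severity-1 (mild) trimmer records of these
  groups are excluded from KPI computation, because mild forms are common,
  usually painless, and inconsistently recorded.

Farmer-app records carry no severity score (the app records only noteworthy
lesions); they are treated as severity 2 by default so they survive the
severity recoding.  The convention is configurable
(`farmer_default_severity`).

## KPI conventions

* **Mean cow number** = total cow-days present in the year / days in the
  year (366 in leap years; the basis is configurable).  Presence is the
  half-open interval [entry, exit).
* **IR_ClawL** counts, in the default `cow-year` mode, each cow at most once
  per lesion group per year ("percentage of cattle with at least one
  documented lesion").  The alternative `cow-visit` mode counts each
  distinct cow × visit-date occurrence as a new case — visits are 4–6 months
  apart, so a recurrence at the next visit is arguably a new episode.  Both
  are implemented and labeled because routine data cannot distinguish
  persistence from recurrence; `cow-visit` is never smaller than `cow-year`.
* **IR_Lame** uses "present at performance testing" = scored that day: cows
  present but not scored are excluded from that date's denominator, since an
  unscored cow's lameness status is unknown.  Dates on which no cow of the
  target group was scored are skipped; a herd whose group is never scored
  reports NaN, not zero.
* **DD-endemic rule**: a herd is endemically infected when strictly more
  than two (≥ 3) distinct cows have an M1–M4.1 record in the year.  The
  wording "at least more than two" is ambiguous; the strict reading is used
  and the threshold is exposed (`dd_endemic_min_affected`).  Non-endemic
  herds report their DD incidence as not applicable (NaN), and only endemic
  herds enter the DD benchmark row.
* **ACR_Claw**: herds with zero culls report 0.0 rather than NaN — half the
  farms in a typical year cull nobody for claw reasons, and they belong in
  the benchmark distribution at zero (the population median is 0).

## Weighted kappa and the observer gate

κ = 1 − Σw·O / Σw·E with disagreement weights w over the declared ordered
scale, observed joint proportions O and chance-expected proportions E (outer
product of the marginals).  **Linear** weights (|i−j|/(K−1)) are the
default, quadratic optional; published kappas from other software often do
not state their scheme, so exact replication of third-party values is not
expected — all reliability checks here are properties (oracle equivalence,
chance-level behaviour, merge monotonicity), not value targets.

Degenerate case: both raters constant and identical gives κ = 1 with a
`degenerate` flag.  Zero expected disagreement with non-zero observed
disagreement is flagged `undefined` (NaN); it cannot arise from a
contingency table but the code path is kept for safety.

Category merging (e.g. the (12)(3)(45) locomotion merge) recodes both
raters onto partition blocks ordered by their lowest member and recomputes
κ on the merged scale.  The gate is inclusive: κ ≥ 0.61 passes; the passed
set feeds the validation stage's trained-observer registry (together with
the app-trained farmer recorders).

## Validation cascade

Record rules (order-independent, all evaluated): the cow must be rostered
in the herd at the record date (`animal-id`); the date must fall in the
study year (`date-window`); the lesion code must resolve (`lesion-code`).
Herd rules, reported in a fixed first-failing order: `no-roster`,
`trained-share` (≥ 95% of records from registry observers), `trim-share`
(distinct trimmed cows ≥ 50% of the mean cow number), `lesion-free` (at
least one no-lesion documentation — a stream that only reports lesions is
not trusted to be complete), `min-diagnoses` (≥ 5 distinct lesion groups).
All thresholds are inclusive ("at least").  The ledger records every
rejection with measured value vs threshold; accepted + rejected = input
exactly, and validation is idempotent.

## Benchmarking

Percentiles use linear interpolation between order statistics (the "type-7"
convention, numpy's default); SD is the sample SD (ddof = 1).  Values are
rounded to one decimal only at rendering.  Lower is better for every KPI in
scope, so the six bands run ≤P10, (P10,P25], (P25,P50], (P50,P75],
(P75,P90], >P90, with boundary values assigned to the better band (matching
the inclusive "good ≤ 10th percentile" reading).  The traditional labels are
attached secondarily — good ≤ P10, moderate ≥ P25 and < P50, poor ≥ P50 —
leaving (P10, P25) unlabeled, as the three-label scheme does.  For a
degenerate constant distribution all cuts coincide and the good label takes
precedence.  The MY FARM column classifies a farm against a table built from
the same year's population; the farm need not be part of the benchmark
population itself.

## The synthetic-data generator

The generator emulates the record streams of a national claw-health
recording scheme for one calendar year (default 2020):

* **Herds and rosters.**  Herd sizes are lognormal, rejection-truncated to
  16–163 with mean ≈ 34.8.  Cows calve every ~380 ± 15 days and are dried
  off 60 days before the next calving (reproduction parameters are the
  package's own choice; they exist to populate the dry and first-100-DIM
  groups, not to model fertility).  28% of cows exit during the year at a
  uniform date and are replaced by heifers entering at first calving, which
  yields realistic mid-year turnover in the cow-days denominator.
* **Trimming visits.**  Two visits (65%) or three (35%), spaced 120–180
  days, starting in late winter/spring; 75% of present cows are trimmed per
  visit; trimmed cows without a lesion that day get an `NL` record.  ~3% of
  lesion records come through the farmer app (no severity score).
* **Lesions.**  Each group g has a per-herd true annual incidence p_g drawn
  from a zero-inflated Beta prior (zero-inflation for the rare groups —
  thin sole, phlegmon, swellings, fissures — reproduces benchmark rows
  whose 10th–75th percentiles are all zero; the Beta spread reproduces the
  long right tails).  The priors are calibrated so the population means
  land near the published incidence pattern for routinely trimmed herds
  (0.7% thin soles up to ~33% DD in endemic herds).  A cow present
  `days` of the year acquires a recorded lesion of group g with probability
  p_g · days/year_days, attached to a visit date clamped into her presence
  window; codes within a group are mixed realistically (e.g. the ulcer
  group splits into sole/toe/bulb ulcers, toe necrosis and the non-healing
  DD-associated variants).  Severity-sensitive groups generate their
  truth-contributing records at severity 2–3, with an independent layer of
  severity-1 noise records on top that the recoding must remove.  25% of
  affected cows get a repeat record at another visit, which separates the
  two counting modes.
* **Why the estimators are exactly unbiased.**  The cow-year numerator is
  the number of distinct recorded cows, whose expectation is
  Σ p_g · days_i/Y = p_g · MCN; dividing by the mean cow number therefore
  recovers p_g without bias.  This is by construction: the generator's
  purpose is to make "the KPI module recovers the truth table" a sharp
  test of the estimator plumbing (denominators, date clamping, severity
  recoding, distinct-cow counting), not a test of detection efficiency.
* **Digital dermatitis.**  A herd is endemically infected with probability
  0.558.  Endemic herds draw p_DD from the DD prior (floored at 0.03) and
  their affected-cow draw is conditioned on at least three affected animals
  — the operational definition of "endemic" — by truncated resampling.  The
  truth table stores the exact conditional expectation E[X | X ≥ 3] / MCN
  (Poisson-binomial), so the recovery test stays exactly unbiased and the
  pipeline's endemic classification agrees with the latent flag herd for
  herd.  Non-endemic herds generate no M-stage records at all.
* **Locomotion.**  Each herd has a true lameness probability θ drawn from a
  Beta with mean 0.383 and SD 0.19 (between-herd spread matching published
  benchmark ranges); conditional on lameness, scores 2–5 follow the
  population multinomial (61.7, 24.2, 8.8, 4.3, 1.0)%/(1−0.617).  Herds are
  scored ~10 times a year at 30–40-day intervals; dry cows are scored with
  probability 0.4 (they are not always presented at performance testing),
  which makes the per-cow scoring count (~6–7) emerge from the schedule and
  turnover rather than being set directly.
* **Culling.**  Exiting cows get a coded culling record with probability
  0.9; the claw & limb reason is chosen with a per-herd propensity that is
  zero for 55% of herds and Beta(mean 0.19, SD 0.15) otherwise — the
  zero-inflation produces the published pattern of a zero median ACR with a
  heavy right tail.
* **Rater tables.**  Reliability exams are simulated by drawing each
  observer's response from a row-stochastic confusion matrix given a
  reference category; identity, uniform and adjacent-error matrices are
  provided.  Adjacent-error confusion is what makes the (12)(3)(45) merge
  provably helpful: 1↔2 and 4↔5 confusions vanish on the merged scale.

One global seed expands into per-herd, per-stream substreams
(`numpy.random.SeedSequence.spawn`), so identical configs give
byte-identical CSVs and adding a stream never perturbs the others.

### What the generator does not emulate

No biologically mechanistic lesion progression or transmission; no
within-lactation autocorrelation of lameness beyond the herd-level effect;
no seasonality; no association between lesions and culling at cow level
(culling propensity is herd-level); trimming and locomotion streams cover
the same herd population, whereas real schemes typically score locomotion
in a smaller subset of herds.  Consequently, passing tests demonstrate that
the estimators, filters and reports compute what they claim on data with
the right marginal structure — they do not validate detection sensitivity,
observer drift or selection effects present in real registry data.

## Problem sizes and numerical choices

The statistical test battery uses 500-herd populations (≈ 45k trimming and
≈ 150k locomotion records), 20 × 10,000-item rater replicates for the
chance-level kappa check, and exhaustive enumeration of all 3×3 rating
tables with cell counts ≤ 3 against a brute-force oracle; these sizes give
Monte-Carlo standard errors small enough for 3-SE assertions while keeping
the whole suite under a minute of compute.  Ties in percentile cuts, NaN
KPIs (never-scored groups, DD-free herds, zero denominators) and degenerate
kappa tables all have explicit, tested conventions rather than incidental
behaviour.

## Known limitations

* Published kappa values cannot be replicated exactly without the original
  rating vectors and the (unstated) weight scheme; the gate's behaviour is
  what is tested.
* The cow-year/cow-visit ambiguity is resolved by configuration, not by
  modelling recurrence.
* National animal-id checksum rules are not implemented; identifier
  plausibility is roster membership only.
* Sub-population benchmarks (by breed, herd size, housing) and
  year-over-year trends are out of scope.
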