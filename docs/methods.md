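# Methods

## The measurement problem

The CCA scores advanced gross motor performance in youth (9–18 years)
recovering from concussion. Each task produces a continuous raw measure —
completion time, repetition count, or jump distance — plus a count of
performance errors (a non-tandem step, a touched pylon, a missed start
line). Two design tensions drive the whole pipeline:

1. **Accuracy before speed.** A fast but sloppy performance must not
   out-score a careful one, so error handling is built into the response
   scale rather than treated as a nuisance covariate.
2. **Healthy athletes sit near the ceiling.** Cut points must be strict
   enough at the top of the scale that a post-injury decline is visible.

## Scoring model

Scoring factors into a bin stage and an error stage.

**Bin stage.** A scoring form holds, per task, an ascending list of raw
cut points: three for the 5-point quartile scale (bins score 1–4), one or
two for the legacy mean ± SD scale. For time tasks the best bin is below
the first cut; for repetitions/distance above the last. A value exactly on
a cut takes the better adjacent bin — anchored by the published example
that a 1.5 m standing long jump scores 4 under a 1.5 m top cut. The
Standing Long Jump bins the maximum distance over its three trials,
counting only trials with a valid two-foot landing, and scores 0 when no
trial is valid.

**Error stage.** Each task carries an error rule `(zero_score_at,
cap_by_errors)`: at or beyond `zero_score_at` errors the item scores 0;
below it the bin score is capped at `cap_by_errors[e]`. The published
anchors are: auto-zero at 1 error for Jumping Jacks and Pylon Obstacle
Course (error prevalence < 5 % in the development sample), at 2 for
Shuttle Run, 3 for Ins and Outs, 5 for Backwards Tandem Walking; one-error
caps of 3 (Backwards Tandem), 2 (Ins and Outs) and 1 (Shuttle Run). The
intermediate caps the published material leaves open are filled in the
only monotone way consistent with those anchors: Backwards Tandem
`cap(e) = max(1, 4 − e)` for 1 ≤ e ≤ 4, Ins and Outs `cap(2) = 1`. Score
0 is reserved for error-driven failure or inability to perform; an
error-free performance never scores below 1.

The three outcome items sum to an unweighted 0–12 outcome summary ("the
three items combined"); the three exertion items remain standalone.

## Cut-point derivation

Only error-free records enter derivation (for the long jump: zero errors
and at least one valid landing), so thresholds describe accurate
performance. Two methods:

* **mean ± SD** (legacy 4-point): cuts at mean ± 1·SD, adding ± 2·SD for
  a second cut, signed toward the worse direction so the best category
  lies beyond mean ± 1·SD on the better side. SD is the sample SD
  (ddof = 1), pinned by the worked example that values (10, 12, 14) with
  one lower-better cut give a threshold of 10 s.
* **quartile** (5-point): cuts at the 25th/50th/75th percentiles using
  numpy's default linear interpolation between order statistics
  (Hyndman–Fan type 7), stated here for bit-reproducibility. Applied back
  to its derivation sample this yields four 25 % bins exactly for
  continuous measures; for integer repetition counts ties at the cuts are
  resolved toward the better bin, so bin occupancies are exact only up to
  tie mass.

Stratified derivation produces the four scoring forms (9–12 / 13–18 ×
female / male, the age bands following the instrument's subgroup
analyses) and requires a configurable minimum of 30 error-free records
per stratum-task (no published floor exists). Forms carry provenance
(sample id, per-task error-free n, method) and round-trip through JSON
bit-exactly.

## Diagnostics

Per item: mean, sample SD, adjusted Fisher–Pearson skewness
(`scipy.stats.skew(bias=False)`), and % at the scale maximum.
`too_difficult` fires when the mean falls below 2.0 on the legacy 0–3
scale (the published acceptability criterion; its "SD of 1.0" clause is
reported but not enforced, being ambiguous). `ceiling_effect` is a
qualitative notion operationalised as > 15 % of scores at the maximum or
skewness < −0.5, both configurable. The two flags are mutually exclusive
per evaluation. Error prevalence (% of participants with ≥ 1 error) feeds
a rule-class recommendation: auto-zero below 5 %, graded caps above.

Note a structural feature of the synthetic world: because quartile cuts
are derived from the same healthy cohort they score, ~25 % of error-free
athletes necessarily occupy the top bin, so the 15 % ceiling flag fires
for most items on the derivation sample itself. The flag is informative
when a form is applied to a *different* (e.g. post-injury) sample.
Likewise, the one-sided mean ± SD convention adopted here places the top
legacy category beyond mean + 2·SD of the same sample, so the legacy
rescore shows floor-like difficulty rather than the ceiling that motivated
the real instrument's revision — there the 4-point cuts had been inherited
from a different (non-athlete) population.

## Reliability

Single-measure ICC from the two-way random-effects, absolute-agreement
decomposition (ICC(A,1)): with subjects as rows and the k = 2 sessions as
columns,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)).

Two-way absolute agreement is the right form because assessors varied
between sessions, so a systematic session shift should count against
reliability; a one-way random-effects ICC(1) is available via
`model="one_way"`. Confidence intervals follow McGraw & Wong's F-based
construction with Satterthwaite degrees of freedom for the session term.
Negative estimates are reported as computed (small-sample ICCs can be
negative); perfect-agreement input returns a degenerate (1, 1, 1)
interval. The estimator is verified against an independent ANOVA
sums-of-squares oracle (1e-10) and cross-checked against
`pingouin.intraclass_corr`; nominal 95 % coverage is confirmed by
simulation (95.2 % over 1000 replicates at n = 50, true ICC 0.7).

Stability bands: ICC < 0.60 unstable, 0.60–0.70 marginal (both endpoints
inclusive, reading "between 0.60 and 0.70" inclusively), > 0.70 stable.
Subgroup tables stratify by retest interval (≤ 12 months → "0–12",
otherwise "12–24", one rule applied uniformly), age band and sex;
subgroups under 4 pairs are flagged `insufficient_n` without an estimate.
Reliability is computed on raw measures (seconds / repetitions / metres),
matching how the instrument's retest table is laid out; ICCs of 0–4 item
scores can be obtained by scoring first and passing scores as values.
`select_outcome_items` retains tasks whose whole-group 0–12-month ICC
exceeds 0.70 as outcome items; fed the published whole-group estimates
(0.56, 0.38, 0.83, 0.48, 0.73, 0.81) it returns exactly the instrument's
three outcome items.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the development design — a cross-sectional
normative cohort (default n = 854, ages 9–18, 50 % male) and a paired
retest cohort (default n = 67, intervals uniform on 0.5–24 months).
Choices, stated once:

* **Families.** Times are lognormal (moment-matched so location/scale are
  the natural-scale mean/SD), repetitions rounded normals truncated at 0,
  jump distances normals truncated at 0 with three trials (per-trial
  noise SD 0.05 m, per-trial landing-failure probability 0.036).
* **Locations/scales** follow the published retest means/SDs where those
  are in usable units (e.g. shuttle run 19 ± 1.6 s, jumping jacks
  23 ± 2.6 reps); the long jump is 1.45 ± 0.25 m, chosen as a realistic
  youth standing long jump because the published table's jump units are
  internally inconsistent. Adolescent and male strata get additive
  location shifts in the better direction, consistent with performance
  improving with age, muscle mass and body proportions.
* **Errors** are Poisson with rates λ = −ln(1 − p), p the published
  per-task error prevalences (1.8 / 2.4 / 55.3 / 11.8 / 25.5 / 2 %), so
  P(≥ 1 error) matches those prevalences exactly in expectation.
* **Retest pairs** are Gaussian `location + subject + occasion` sums with
  the between-subject share of variance equal to the task's `true_icc`
  (default: the published whole-group 0–12-month estimates). The realized
  variance of the stratum location shifts is subtracted from the latent
  subject-effect budget so the population ICC equals `true_icc` exactly;
  calibration is verified at n = 5000 within ±0.02. The cross-sectional
  families are deliberately *not* reused here: a nonlinear (lognormal)
  transform of an additive decomposition would not preserve the target
  ICC.

Not modelled: anthropometrics, practice/learning effects between
sessions, assessor effects beyond the session shift the ICC form absorbs,
correlation between tasks within athlete, and any attempt to reproduce
the real sample's empirical cut points. A green test therefore
establishes that the *machinery* (filtering, derivation, scoring, ICC
estimation, classification) is correct under a known data-generating
process — not that the synthetic cut points or ICC tables match the
licensed instrument's values.

## Numerical and degenerate-case conventions

* Determinism: one global seed; per-task and per-purpose sub-streams are
  derived through `numpy.random.SeedSequence` with stable string-hash
  keys, so adding a stream never perturbs existing ones.
* Zero-variance derivation input yields coincident cut points plus a
  degeneracy warning rather than an error.
* `icc_single` requires ≥ 4 pairs and finite values; the pipeline reports
  rather than raises for small subgroups.
* CSV schema validation rejects negative times/errors, unknown sex or
  session labels, and missing demographics with row-addressed messages.
* Seeded pipeline runs are byte-identical end to end; the manifest stores
  artifact paths relative to the output directory plus SHA-256 checksums.
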