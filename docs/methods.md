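# Methods

## Input model

The unit of analysis is a *time-aligned token sequence*: an ordered list of
labelled intervals a phone-level recognizer emits for one monologue —
phones, silent pauses, and filled pauses (hesitation vocalizations the
recognizer outputs as labelled tokens, like phones).  Category assignment is
configuration (a `LabelMap` binding the recognizer's symbol inventory to the
three categories), never inferred from label strings.  CTM is the canonical
exchange format (textual, one timed token per line); Praat TextGrid interval
tiers are read with the convention that empty interval labels are silent
pauses while filled pauses must be explicit labels.

### Normalization

Before feature extraction a timeline is canonicalized, in this order:
unlabelled gaps become silent pauses (phone-level recognizer output is
exhaustive, so gaps only occur in third-party alignments); runs of adjacent
silent pauses merge; silent pauses shorter than `min_pause_s` are dropped
from the pause inventory (their span stays inside the utterance but counts
toward no pause statistic); leading/trailing silences are deleted outright
when `trim_edges` is on.  Defaults: `min_pause_s = 0.03` s — below about
three recognizer frame steps an alignment gap is not credible as a planned
pause — and `trim_edges = true`, because recording lead-in/out silence is a
session artifact, not speech planning.  Neither choice is standardized in
the field, so both are configuration, and trimming is logged since it
changes utterance length.  Normalization is idempotent.

## Feature definitions

The fifteen TSPs are evaluated literally from the normalized token list (see
README for the formula table).  Two deliberate interpretations:

* "number of phones" counts phone-category tokens only; pause tokens never
  count as phones, otherwise articulation tempo would depend on pause
  segmentation;
* a pause average duration with zero pauses in its scope is *missing*
  (NaN), never 0 — zeros would bias group means downward for pause-free
  speakers.  Downstream statistics exclude missing cells per variable and
  report the reduced n.

Multi-utterance subjects are supported by concatenating token sequences with
no pause contributed at recording boundaries (the reference design has one
monologue per subject).

## Statistical chain

* **Test choice (raw data).**  Shapiro–Wilk (default) or
  Lilliefors-corrected Kolmogorov–Smirnov at α = 0.05 per group; any
  non-normal group sends the variable to Mann–Whitney U.  Otherwise Levene
  (mean-centred) at α = 0.05 picks Welch vs pooled-variance *t*.  Constant
  samples, on which normality tests are undefined, fall through to
  Mann–Whitney.
* **Test choice (summary mode).**  Printed tables carry only (n, M, SD), so
  the variance gate is the two-sided variance-ratio *F* test.  On the
  bundled reference summaries this reproduces the published pooled/Welch
  split exactly on all fifteen rows (largest pooled-row ratio F = 1.84,
  smallest Welch-row ratio F = 2.24, critical value ≈ 2.08 at these group
  sizes).
* **Sign conventions.**  The *t* statistic is control − case with the
  control group listed first; Cohen's d is case − control over the
  n−1-weighted pooled SD, so a case-elevated variable has positive d.  The
  two therefore carry opposite signs; both are stated on the result objects.
* **Mann–Whitney.**  U counts case–control pairs won by the first group
  (ties half); z uses the tie-corrected variance with no continuity
  correction; the default p is the two-tailed normal approximation (the
  package convention at these group sizes), with an exact-U option for
  small untied samples.
* **Pruning.**  Pearson correlations on pairwise-complete observations; a
  greedy scan in relevance order drops any variable with |r| > 0.9 against
  an already-kept one, recording the kept proxy.  "Relevance" defaults to
  descending |Cohen's d| — the natural operationalization of "keep the most
  relevant of a correlated pair" — and is overridable.  The retained set is
  data-driven output, never a hard-coded list.  Constant columns have
  undefined correlations: they are kept and flagged.
* **ROC.**  Per-variable empirical AUC via midranks (identical to all-pairs
  counting with ties at half weight); direction set from group means (case
  mean higher → higher values predict case status); Hanley–McNeil
  nonparametric SE (Q1 = A/(2−A), Q2 = 2A²/(1+A)); two-tailed normal test
  of AUC = 0.5; Bonferroni gate at α/m with m defaulting to the kept-set
  size.  Cut-point candidates are midpoints between consecutive distinct
  scores plus ±∞ sentinels; the Youden maximizer is reported with ties
  broken toward higher sensitivity, then the lower (oriented) cut-point.
  The published SE estimator behind such tables is typically unstated;
  Hanley–McNeil is the standard nonparametric default, and exact SE
  reproduction is not claimed.  At the reference group sizes the asymptotic
  normal test is mildly anti-conservative far in the tail (measured ≈0.9%
  tail mass at nominal 0.45%), so family-wise null survival sits near 10%
  rather than the nominal 5% — a property of the estimator, documented
  rather than patched.

## Cohort simulator

Real clinical recordings are not distributable; printed group summaries
are.  The generator emulates a published 31-control / 34-AUD comparison by
sampling six *free* per-subject quantities and building a timeline from
them deterministically, which makes the generator exactly invertible by the
feature engine (`compute_tsp ∘ construct_timeline` reproduces every implied
TSP to numerical precision — a sharp oracle used throughout the tests).

Per group, the free quantities and their families:

| quantity | family | control target (M, SD) | AUD target (M, SD) |
|---|---|---|---|
| utterance length (s) | truncated normal, [15, 300] | 84.052, 34.760 | 77.569, 44.481 |
| articulation tempo (phone/s) | truncated normal, [8, 22] | 14.743, 1.544 | 14.551, 1.186 |
| silent pause occurrence rate (%) | truncated normal + Poisson counts | 4.850, 1.628 | 5.243, 1.907 |
| filled pause occurrence rate (%) | truncated normal + Poisson counts | 1.512, 0.897 | 2.831, 1.695 |
| silent pause avg duration (s) | log-normal | 0.641, 0.155 | 0.983, 0.488 |
| filled pause avg duration (s) | log-normal | 0.243, 0.078 | 0.246, 0.090 |

Numerical choices that matter:

* **Moment-matched truncation.**  Truncating a normal at asymmetric
  physiological bounds shifts its mean, so the location is solved
  numerically per spec so the *truncated* mean equals the target (for the
  AUD utterance length, naive truncation at 15 s would bias the mean by
  ~2 s, several Monte-Carlo SEs at calibration scale).
* **Count variance decomposition.**  Realized pause counts are Poisson with
  intensity rate/100 × phone count.  The printed SD of an occurrence rate
  is the *total* across-cohort SD, so the across-subject heterogeneity SD
  is set to √(SD² − mean Poisson variance of the realized rate); stacking
  Poisson noise on top of the printed SD would over-disperse every derived
  tempo statistic.
* **Sampling order.**  Articulation tempo, length, rates and durations are
  drawn; the phone count is fixed at the fixed point n = AT·L/(1 + AT·g/100)
  (g = Σ rate × duration / subject); counts are then drawn and the realized
  utterance length re-derived as n/AT + realized pause time.  This makes
  every free TSP exactly unbiased for its target mean; letting the length
  stay fixed and re-rounding the phone count instead leaves a Jensen-type
  bias in the occurrence rates.
* **Within-subject structure.**  Phones get equal durations and all pauses
  of a scope share the subject-level duration; the fifteen TSPs are
  insensitive to within-utterance duration variation, so the variation that
  matters (across subjects) carries all of the modeled variance.  Pause
  positions are uniform over distinct internal phone boundaries, never at
  the edges, so constructed timelines are already in normalized form and
  survive a CTM round-trip through the extraction pipeline unchanged
  (generated pauses are also never shorter than the default minimum-pause
  threshold).
* **Independence.**  The published marginals carry no joint information;
  free parameters are sampled independently.  Consequences: derived TSPs
  (speech tempo, duration rates, frequencies) emerge near — not exactly at
  — their published values (within ~10% relative at calibration scale), and
  the pooled speech-tempo Cohen's d recovers to about −0.95 against the
  published −0.971, the SDs of derived quantities being mildly inflated by
  the independence assumption.  One published cell is internally
  inconsistent with the free parameters it must emerge from: the AUD filled
  pause duration rate is printed as 6.914 while the printed filled-pause
  frequency × average duration gives ≈6.0 and the full composite ≈5.5;
  under independence the simulated mean lands near the composite value,
  and the calibration test checks it against that implied value.
* **Seeding.**  One global seed; per-subject substreams derive from a
  stable hash of (group, index), so enlarging one group never changes
  another group's subjects and cohorts are bit-reproducible.

### What passing simulator-based tests does and does not show

The generator matches first moments of the free parameters, the sign
pattern of all ten published significant group differences, and the
headline effect size.  It does not model lexical content, within-utterance
tempo drift, pause-position clustering, parameter correlations within
subject, or recording/ASR noise — so simulator-based results demonstrate
correctness and calibration of the *pipeline*, not clinical validity on
real speech.

## Degenerate inputs and edge rules

Timelines with no phone content raise a dedicated degenerate-input error
(the CLI skips such subjects with a warning and only fails if nothing
survives).  Zero-pause speakers get missing average durations.  Both-SD-zero
summary pairs make the t statistics undefined and raise.  A ROC variable
with a single distinct score yields J = 0 with a warning.  Division-free
identities (occurrence/duration/frequency additivity across scopes, speech
tempo ≤ articulation tempo with equality iff no pause time) are asserted as
property tests over random timelines.

## Problem sizes

Calibration measurements use 10,000 subjects per group (Monte-Carlo SE of a
group mean ≈ SD/100, making 3-SE checks meaningful at the printed
precision); effect-direction checks are already stable at 2,000 per group;
the type-I-error calibration uses 1,000 null replicates at the reference
group sizes (31/34).  The full suite runs in under a minute on one CPU.

## Known limitations

* Summary mode cannot screen normality; it trusts that printed rows were
  already screened (as such tables conventionally are).
* The Hanley–McNeil SE underestimates far-tail dispersion slightly at
  n ≈ 30/group (see above); a covariance-based estimator could be slotted
  in behind the same interface.
* TextGrid support covers the long and short *text* formats, interval tiers
  only (point tiers carry no durations); binary TextGrids are out of scope.
* No multivariable classifier is built: variables are evaluated one at a
  time, matching the analysis the package reproduces.
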