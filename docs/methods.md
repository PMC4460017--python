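# Methods

## Problem and model

`actitime` estimates how a person's day divides among five activities —
walking, sitting, running, lying down and dynamic standing — from two
body-worn accelerometers, one on the upper arm and one on the thigh.
Each device reports per-axis acceleration averaged over 5-second epochs
and a step count accumulated per minute.  One classification instance
("sample") is a 5-s epoch carrying both sites' epoch means plus both
sites' steps/min, broadcast unchanged from the enclosing minute; with
biaxial devices this is a 6-vector (arm x, y, steps; thigh x, y, steps),
with triaxial devices an 8-vector adding both z axes.

*Dynamic standing* is standing with possible upper-body movement and
incidental stepping below 30 steps/min; walking below that rate is,
by definition, dynamic standing.  This operational boundary is built
into preprocessing: any per-site step count strictly below 30 steps/min
is set to 0 before classification, so incidental stepping cannot
masquerade as locomotion while genuine walking (>30 steps/min) retains a
strongly discriminative feature.  The comparison is strict (`<30 → 0`,
exactly 30 kept); an inclusive variant is available via
`ThresholdRule(comparison="le")`.  The threshold is applied at training
*and* prediction time (flag `threshold_at_inference`, default on): a
kernel classifier must see the same feature distribution at both stages.
Step counts stay in steps/min; no unit conversion is applied.

The classifier is a soft-margin support-vector machine with a radial
basis kernel on the raw feature units:

- kernel: `K(u, v) = exp(-gamma * ||u - v||^2)`, `gamma = 0.01`
- cost `C = 10`
- multiclass: pairwise one-vs-one with majority voting
- dual stopping tolerance `1e-3` (recorded in the model container)
- no feature standardization by default (`standardize` flag exists but
  is off: the quoted cost/gamma refer to raw features)

Vote ties resolve to the class with the lowest canonical index.  The
underlying solver (libsvm via scikit-learn) implements exactly this
convention: its voting loop keeps the earliest class on equal votes, and
classes are ordered by canonical index.  With continuous features an
exact vote tie has probability zero, so the rule matters only as a
determinism guarantee.

Time use is aggregated from the predicted label sequence as
`seconds(activity) = 5 s × count(activity)`, with proportions over
classified time; an empty sequence yields a zero budget with proportions
flagged undefined rather than NaN.

## Synchronization and labeling

Epochs are half-open windows `[t, t+5)` with timestamps at the window
start and whole-second precision; streams must sit on an absolute 5-s
grid and step readings on the 60-s grid.  Fusion emits one sample per
epoch present in *both* acceleration streams whose enclosing minute has
step readings at both sites (epochs missing step data are dropped and
logged); the minute's count is broadcast to its twelve epochs.

Diary intervals are half-open, non-overlapping, 1-s precision.  A sample
takes the label of the interval containing its full window; windows
straddling a boundary stay unlabeled.  Training mode additionally drops
samples near activity transitions: with `drop_transitions` and a guard
of `guard_s` seconds (default 0), any window overlapping the open band
`(boundary − guard, boundary + guard)` is excluded — a deterministic
surrogate for pruning transition samples by hand.  Scoring mode keeps
unlabeled samples so they can be excluded from the confusion matrix
explicitly.

## Validation statistics

All statistics derive from a square confusion matrix of real (rows) ×
classified (columns) epoch counts in the canonical order walking,
sitting, running, lying down, dynamic standing — the order fixed by the
reference results this package regression-tests against.

- sensitivity `c_ii / row_i`, positive predictive value `c_ii / col_i`,
  specificity `TN_i / (TN_i + FP_i)`, F-score the harmonic mean of
  sensitivity and PPV, overall accuracy `trace / n`.
- Cohen's kappa `(p_o − p_e) / (1 − p_e)` with `p_o = trace/n`,
  `p_e = Σ row_i col_i / n²`.
- Weighted kappa with agreement weights `w_ij = 1 − d` (linear) or
  `1 − d²` (quadratic), `d = |i − j| / (k − 1)`: `p_o,w = Σ w_ij c_ij / n`,
  `p_e,w = Σ w_ij row_i col_j / n²`.  Weighted kappa is order-dependent
  by construction; permutation tests assert this rather than "fix" it.
- Undefined ratios (empty class) are reported as `None` and excluded
  from group summaries instead of being coerced to zero, which would
  bias per-person means.
- Group comparisons: exact two-sided Wilcoxon matched-pairs signed-rank
  test (zero differences dropped; all-zero flagged with p = 1) and
  Welch's unequal-variance t-test with Satterthwaite degrees of freedom
  (zero variance in both groups with equal means flagged with p = 1).
- `merge_classes` sums the rows and columns of a class group (count
  conserved), used to quantify how much of the walking/dynamic-standing
  confusion is internal to that pair.

Two pooled reference matrices (confined-environment, n = 6512, and
free-living, n = 198 445) ship as CSV data files; the test suite and the
acceptance script recompute their kappas, per-class diagnostics, pooled
accuracy, merged-pair sensitivity and row-total time shares from these
counts at run time.

## Synthetic sessions

The generator exists so every pipeline stage has a known-answer regime;
it makes no attempt at biomechanical realism (no gait harmonics, no
gravity-orientation drift, no biking/stairs).

**Protocols.** The confined-environment session is 22 bouts of
2 minutes each — activity variants totalling 4 lying, 5 sitting,
5 dynamic standing, 5 walking, 3 running — in a fixed canonical order
(`ce_ordered`) or a seeded permutation (`ce_random`), mirroring a
supervised laboratory protocol in which a researcher logs bout
boundaries.  The free-living session (`ue_diary`) is 24 h of 10-minute
bouts apportioned by largest remainder to target shares of 37% lying,
45% sitting, 12% dynamic standing, 5% walking, 1% running — a typical
mostly-sedentary day — and shuffled into a seeded order; per-class
totals land within one bout of their targets.  A configurable
`unannotated_fraction` (default 0) withholds a seeded subset of bouts
from the returned diary while still generating their signal, exercising
the unscored-time path.

**Signals.** Per-epoch accelerations are normal draws from per-activity,
per-site profiles; device units are arbitrary.  The default x/y means
(SD 2–4) separate the five classes; the z axis has one shared
distribution (mean 8, SD 2) for every activity, so six- and
eight-feature classifiers receive the same class-relevant information —
the regime in which adding z should not help.  Step counts are drawn
once per minute (the device's native granularity): a shared gait-rate
draw per minute plus an independent per-site jitter of ≤2 steps.
Default base ranges are 0 for lying/sitting (exact, so resting minutes
count 0 steps), 0–27 for dynamic standing, 62–118 for walking and
142–178 for running; with jitter the realized counts respect the
operational definitions (standing < 30, walking > 30, running ≥ 140).

**Hard regime.** `default_profiles(standing_walk_overlap=o)` degrades
exactly the walking/dynamic-standing distinction.  The dial (i) moves
the standing acceleration means toward walking's (identical at `o = 1`),
(ii) pulls both step ranges toward the 30 steps/min boundary — at
`o = 1` standing reaches 29 and slow walking straddles the threshold at
27–36, the definitional ambiguity of short-distance walking — and (iii)
shrinks the per-site jitter to zero so near-threshold minutes are zeroed
consistently at both sites.  Without (iii), minutes zeroed at one site
but not the other produce feature vectors far (in kernel distance) from
every training cluster, and their one-vs-one votes are decided by
classifier biases — scattering errors into unrelated classes instead of
the intended pair.

**What passing tests do and do not show.** With the default separable
profiles the full pipeline recovers ≥ 90% of epochs on an unseen
simulated day (in practice ≈ 100%), which validates the plumbing —
synchronization, thresholding, training, scoring — not field
performance: real accelerometry has transitions, within-class
heterogeneity and annotation error that the generator only caricatures
(the guard-band exclusion and the overlap dial probe those mechanisms
qualitatively).

## Numerical choices and edge cases

- Deterministic everywhere: sessions derive all randomness from
  `SeedSequence([seed, ...])` children; training is deterministic given
  identical data and config; reruns are bit-identical.
- Confusion-matrix counts must be integers; kappa is flagged undefined
  (not NaN) when `p_e = 1` (all mass in one row-column pair).
- Scheduled bouts are whole minutes, so every minute has a single
  activity; the generator still assigns each minute the activity with
  majority overlap to stay well-defined under custom schedules.
- Display rounding (kappas to 2 decimals, percentages to integers)
  happens only in the reporting layer; exact values are carried
  alongside.

## Known limitations

- The acceleration profile constants are invented; nothing ties their
  scale to a physical device, only their separability structure matters.
- No temporal smoothing or sequence model on the label stream;
  transitions are excluded (training) or scored as-is (validation).
- Per-person dispersion statistics can be computed from per-person label
  sequences, but the shipped reference matrices are pooled only, so the
  reference ± figures are not recomputable from shipped data.
- Biking and stair climbing are outside the five-class universe by
  design; such inputs are forced into the nearest trained class with no
  rejection option.
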