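# Methods

`eegsex` implements an entropy-feature pipeline for sex recognition from
multichannel resting-state EEG, with a hybrid random-forest leaf-embedding
+ logistic-regression classifier and a nested cross-validation harness.
This note records the models, the parameter choices and their rationale,
what the synthetic cohort does and does not emulate, and the numerical
conventions.

## Signal model and preprocessing

A recording is a channels × samples matrix at sampling rate `fs` with 10–20
channel names and a subject sex label. The preprocessing chain is the
standard resting-state sequence:

1. **50 Hz notch** — second-order IIR notch (`scipy.signal.iirnotch`),
   quality factor Q = 30 by default. The notch frequency and Q are
   configurable; Q = 30 gives a ~1.7 Hz-wide rejection band at 50 Hz.
2. **0.15–45 Hz band-pass** — 4th-order Butterworth (SOS form).
3. Both filters are applied forward–backward (`filtfilt`/`sosfiltfilt`),
   i.e. zero-phase, so epoch boundaries are not shifted by group delay.
   The effective magnitude response is squared (≈ −21 dB at 60 Hz for the
   band-pass).
4. **Final-segment retention** — the trailing 300 s (5 min) are kept; the
   settling period at the start of a session is discarded.
5. **Epoching** — non-overlapping 1-s windows; a trailing partial window
   is discarded, never padded, so a 300-s recording yields exactly 300
   epochs. Epochs are half-open sample intervals `[k·N, (k+1)·N)`.

Filter designs (order, Q) are conventions of this package — acquisition
software rarely documents its filters — and are surfaced as configuration
so they can be matched to a given dataset. Re-referencing and artifact
rejection are out of scope; mastoid referencing is assumed done upstream.

## Entropy estimators

All four estimators operate on a single epoch/channel series `x` of
length N; logarithms are natural (nats).

* **Tolerance**: `r = r_coeff · SD(x)` with the *population* SD of that
  epoch's channel series, default `r_coeff = 0.25`. Each 1-s window is
  treated as its own stationary segment, so the tolerance adapts per
  epoch per channel and the estimates are amplitude-independent.
* **Approximate entropy** (m = 2): `ApEn = Φ^m − Φ^{m+1}` with
  `Φ^k = mean_i ln(C_i^k)`, `C_i^k` the fraction of length-k templates
  within Chebyshev distance r of template i, self-matches included.
  Always finite. Known bias: for white noise ApEn rises as r falls only
  down to r ≈ 0.2·SD, then turns back down as self-matches dominate; the
  default 0.25·SD sits above that regime.
* **Sample entropy** (m = 2): `SampEn = −ln(A/B)` over ordered template
  pairs (i ≠ j) of lengths m+1 and m, both counted over the same N − m
  template start points, self-matches excluded. When A or B is zero the
  estimate is undefined; such cells are *flagged* (NaN + mask), and
  epochs containing flags are dropped from model fitting with a logged
  count rather than imputed. At N = 1000 and r = 0.25·SD this is rare.
* **Fuzzy entropy** (m = 2, n = 2): templates are mean-centred
  (each template minus its own mean), similarity is the fuzzy membership
  `D_ij = exp(−(d_ij/r)^n)`, and `FuzzyEn = ln φ^m − ln φ^{m+1}` with
  `φ^k` the grand mean similarity over i ≠ j. The membership is written
  in the dimensionless ratio d/r so that FuzzyEn, like ApEn and SampEn,
  is exactly invariant under affine transforms of the signal when r is
  tied to the SD; the variant with `exp(−d^n/r)` found in part of the
  literature loses that invariance for n ≠ 1, which would make values
  depend on amplifier gain. At extreme d/r (r orders of magnitude below
  the signal scale) every membership underflows to zero; the estimate is
  then flagged undefined rather than fabricated.
* **Permutation entropy** (order 4, delay 1, normalised): Shannon
  entropy of the ordinal-pattern distribution, ties ranked by order of
  appearance (stable sort), divided by `ln(order!)` so the value lies in
  [0, 1]. Order 4 with 1000-sample windows leaves ≈ 42 patterns per
  ordinal class, enough for a stable census; a warning is emitted when
  `order!` exceeds the number of available patterns.

## Feature matrix and normalisation

Features are laid out channel-major, then measure, in the canonical
order (FE, SE, AE, PE) — 30 channels × 4 measures = 120 columns for the
full montage. Min–max scaling to [−1, 1] has two grouping modes:

* `per_subject` (default): each subject's epochs are scaled by that
  subject's own per-feature min/max. This mirrors the common protocol of
  normalising per subject over the whole dataset before cross-validation.
  Note what this implies: any *between-subject level difference* in a
  feature is removed by construction, because every subject's range maps
  onto the same interval. It also uses each subject's full data,
  including future test epochs (a mild form of leakage, label-free).
* `global`: one min/max per feature over all epochs. Passing the stats
  fitted on a training split to the test split (values clipped to
  [−1, 1]) gives the leakage-safe variant.

Constant features map to 0. Undefined cells stay flagged through
normalisation.

## Hybrid classifier

1. Fit a random forest (default 200 trees, depth ≤ 5, Gini, bootstrap +
   random feature subsets) on the training features.
2. Re-express every sample as the concatenation of one-hot indicators of
   the leaf it reaches in each tree. Leaf columns are tree-major with a
   stable depth-first, left-child-first leaf enumeration per tree, so the
   encoding is reproducible given the forest seed. Each tree's block is
   exactly one-hot per sample; rows sum to the tree count.
3. Fit logistic regression (liblinear; default lasso penalty, C = 1.0,
   tol = 1e−4, iteration cap 1000 with a logged convergence warning) on
   `[leaf one-hot ‖ original features]`. Original features arrive already
   in [−1, 1] and leaf indicators are {0, 1}, so no further scaling is
   applied. The linear coefficients on each tree's leaf block act as that
   tree's weights; no separate per-tree scalar is fitted.

The encoded design strictly extends the plain logistic design, so the
hybrid's training AUC dominates plain logistic regression's on the same
data. No class weighting is applied (accuracy is reported on the
imbalanced 4500/3900 epoch design as-is).

## Evaluation harness

* **Nested CV**: stratified 10-fold outer loop; inside each outer
  training set, an inner 10-fold grid search over (nt, md, penalty, C)
  selects hyperparameters by mean accuracy. Ties break toward smaller
  nt, smaller md, l2 before l1, then larger C (fully specified because
  ties are common on saturated data). The inner loop provably never sees
  outer-test samples; each fold result records the index pool the inner
  search drew from, so the no-leakage property is asserted in tests.
  With no grid (the default for single runs) the defaults nt = 200,
  md = 5, l1, C = 1.0 are used everywhere; sweep-style grids
  (nt ∈ {1,10,20,50,100,200,500,1000,2000}, md ∈ {1..10,20},
  C ∈ {0.001,0.01,0.1,1,10}) are provided as module constants.
* **Fold granularity**: the default splits at the epoch level,
  reproducing the common protocol in which epochs of one subject can
  appear in both train and test. This is a known leakage caveat — a
  model can partially memorise subjects — so a subject-grouped mode
  (`groups=subject_ids`, StratifiedGroupKFold) is provided; it is the
  correct measurement whenever the question is generalisation to new
  subjects, and it is what the no-signal null check uses.
* **Metrics**: accuracy at threshold 0.5 (boundary counts as positive;
  positive class = female) and trapezoidal AUC over all distinct score
  thresholds, identical to the normalised Mann–Whitney U statistic
  (verified against a pair-counting oracle). Mean ROC curves across
  folds are vertically averaged on a fixed 101-point false-positive-rate
  grid.
* **Group comparison**: Welch's unpaired two-sample t test per feature
  between female and male epochs, α = 0.01. A paired test is sometimes
  named for this comparison in the literature, but groups formed by 13
  vs 15 subjects' epochs have no pairing, so the unpaired Welch test is
  the defensible choice. The comparison is computed on raw entropy
  values (the interpretable scale), not on normalised features.
* **Robustness sweeps**: electrode count (random m-of-n channel subsets,
  10 repeats each), test fraction (stratified random splits, infeasible
  fractions skipped with a warning), and sex ratio (the 27 subject-count
  cases {13:1 … 13:15, 12:15 … 1:15}, subjects sampled without
  replacement with all their epochs). Sweeps reuse the default
  hyperparameters unless a grid is passed, and evaluate with stratified
  hold-out splits rather than full nested CV to keep the combinatorics
  tractable.

## Synthetic cohort

No public recordings exist for this study design, so a generator
provides the test bed. Each channel of a subject is a regularity mixture

    x_c(t) = ρ · osc_c(t) + (1 − ρ) · n_c(t)

with a unit-variance sinusoid at a subject-specific alpha-band frequency
(uniform 8–12 Hz, random phase per channel) and unit-variance pink noise
(1/f spectral shaping of white noise — deterministic given the seed, no
filter warm-up). The mixing weight is

    ρ = clip(ρ_sex + N(0, τ) + N(0, σ_ch), 0.01, 0.99),

with ρ_male = ρ0 + δ and ρ_female = ρ0 − δ. Defaults: ρ0 = 0.5, δ = 0.3,
τ = 0.05 (between-subject SD), σ_ch = 0.02 (channel jitter); cohort
geometry 13 male + 15 female subjects, 30 channels, 1000 Hz, 300 s, 1-s
epochs → 8400 epochs (4500 female, 3900 male), 300 per subject. Higher ρ
means more regular signal and lower entropy, so female epochs carry
higher entropy — the direction reported for real cohorts. δ = 0 with
τ = σ_ch = 0 makes the sexes statistically exchangeable (the no-signal
null). Subject seeds are spawned from the master seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and
subjects independent.

**What the generator does not emulate.** Real EEG artifacts, volume
conduction, channel covariance, non-stationarity across the session, and
— importantly — any within-subject structure that would survive
per-subject min–max normalisation. In this generator the sex signal is
purely a between-subject *level* shift in entropy; per-subject min–max
maps every subject's range onto [−1, 1] and therefore removes most of
that signal (measured: hybrid nested-CV accuracy ≈ 0.62 per-subject vs
≈ 0.98 global at the reduced scale below). Real cohorts evidently retain
separability under per-subject scaling, which means their discriminative
structure is partly within-subject — a property this simple mixture does
not reproduce. Consequently the classification experiments on the
synthetic cohort use global normalisation; passing them demonstrates the
pipeline's correctness and the entropy→sex direction, not that
per-subject-normalised real EEG would behave identically.

Because epochs cluster within subjects (each subject has its own
oscillation frequency), epoch-level significance tests are
anti-conservative under the null; null checks therefore operate at the
subject level (per-subject mean entropy, or subject-grouped CV).

## Problem sizes used in the shipped checks

* Dataset-geometry counts run at the full cohort geometry (1000 Hz,
  300 s) with 2 channels — channel count does not enter epoch
  arithmetic.
* The qualitative-reproduction experiments run at a reduced scale chosen
  as the package's desk-scale configuration: 28 subjects, 6 channels,
  60 one-second epochs each at 128 Hz (1680 epochs, FE features). At
  this scale the group difference is overwhelming (Welch p ≪ 0.001 on
  every channel) and all three classifiers operate near ceiling, so the
  orderings (hybrid ≥ RF, hybrid ≥ LR; accuracy non-decreasing in
  channel count; accuracy lower at test fraction 0.95 than 0.2) hold
  with ties allowed.
* Entropy oracle checks compare the vectorised estimators against
  explicit per-template-loop references on 50 random series of lengths
  50–300 at 1e−10 absolute tolerance.

## Numerical conventions and degenerate inputs

* Natural logarithms throughout; normalised PE is unitless in [0, 1].
* Constant series: tolerance r = 0 with a warning; ApEn/SampEn/FuzzyEn
  all return exactly 0 (identical templates), PE returns 0.
* A strictly monotone series has a single ordinal pattern → PE = 0.
* SampEn with zero match counts and FuzzyEn under membership underflow
  return NaN and are masked, never imputed.
* Threshold 0.5 is boundary-inclusive for the positive class; thresholds
  must lie strictly inside (0, 1).
* All randomness flows from explicit integer seeds (numpy Generators,
  sklearn `random_state`); identical seeds reproduce every reported
  number bit-for-bit.

## Known limitations

* The generator's claim is controllability, not physiological realism.
* Epoch-level CV overstates subject-level generalisation; use grouped
  mode for deployment-style claims.
* ApEn's small-r bias means r well below 0.2·SD should be avoided, or
  SampEn/FuzzyEn preferred.
* EDF files are read (via mne); writing is delimited-only.
* Binary classification only; no calibration of predicted probabilities.
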