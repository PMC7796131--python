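# Methods

This note documents the models, parameter choices and limitations behind
`gaitablation`: what the synthetic study generator emulates, how each
analysis stage is defined, and which design decisions were genuinely open.

## 1. The synthetic study

### Protocol

A default study comprises five subjects performing six trials each. A trial
is a 150 s self-paced treadmill session driven by a schedule of fifteen
10 s commands drawn from {stand, walk, run, sprint}. Command orders are
seeded permutations with repetition; the per-subject schedule generator
threads a shared set of uncovered ordered activity pairs through the six
trials, so every transition (including repeats) occurs at least once per
study — the "roughly even distribution of transitions" a balanced protocol
aims for.

### Subject profiles

Each subject carries speed thresholds (walk band (0, v_w], run band
(v_w, v_r], sprint above v_r), preferred steady-state speeds, a response
lag and a stride-frequency base. The five built-in profiles use the
threshold sets

| subject | v_w (m/s) | v_r (m/s) |
|---|---|---|
| S1 | 1.3 | 2.4 |
| S2 | 1.6 | 3.3 |
| S3 | 1.6 | 2.8 |
| S4 | 1.4 | 2.5 |
| S5 | 1.2 | 2.7 |

Preferred walk and run speeds sit at the band midpoints. Sprint bands are
unbounded above, so the midpoint rule cannot apply; the default sprint
preferred speed is v_r + 0.8 m/s, a modest but clear margin for
non-athlete subjects. Response lags are 0.9–1.3 s, stride-frequency bases
0.90–1.00 Hz (full gait cycles; stride frequency rises gently with speed as
f = base · (0.7 + 0.3 v)).

### Treadmill speed

The noise-free speed is the exact first-order lag response toward the
commanded activity's preferred speed (time constant = response lag),
evaluated segment-by-segment in closed form. The *recorded* speed channel
adds zero-mean Gaussian measurement noise (SD 0.05 m/s) and clamps at zero.
All other modalities are synthesized from the noise-free speed: muscle and
force dynamics follow the subject's actual locomotion state, not the speed
sensor's noise. This separation is physically motivated and makes the
generator's amplitude contracts exact.

### sEMG (surrogate model)

The sEMG model is a statistical surrogate, not a physiological simulation.
Its carrier is a unit-RMS blend of two band-limited Gaussian noises
(20–150 Hz and 150–450 Hz, 4th-order Butterworth band-passes, zero-phase);
the per-activity, per-segment blend weight sets the median frequency, an
RMS gain sets the amplitude, and a gait-cycle cosine envelope (RMS-
normalised, legs half a cycle out of phase) adds stride modulation.
Defaults (gain / high-band weight per activity stand→sprint):

- shank: gain 0.05 / 0.25 / 0.65 / 0.85, weight 0.15 / 0.35 / 0.65 / 0.80
- thigh: gain 0.05 / 0.30 / 0.45 / 0.55, weight 0.20 / 0.40 / 0.50 / 0.55

The walk→run contrast — in both amplitude and median frequency — is
deliberately larger for shank muscles than thigh muscles. This is the
planted structure that lets the ablation analysis recover the
lower-leg-beats-upper-leg ordering; it mirrors the physiological
observation that upper-leg muscles have similar EMG profiles in walking
and running while lower-leg profiles diverge.

### Accelerometers

Tri-axial streams in units of g: constant gravity on the vertical axis plus
first and second stride harmonics whose amplitude is `speed_gain[segment] ·
speed` (shank 0.55, thigh 0.22 g·s/m), with 0.03 g sensor noise. Distal
segments see larger accelerations at equal speed because linear
acceleration grows with distance from the centre of rotation; the gain
ratio encodes exactly that. At standstill the harmonics vanish and the norm
is 1 g.

### Force plates

Vertical forces only, in newtons, body mass 69.6 kg by default (study-level
config, since per-subject masses are not part of the profile). Standing
splits body weight evenly with slow antisymmetric sway (15 N at 0.3 Hz).
Gait alternates left/right stance windows at the stride frequency with an
activity-dependent duty factor — walk 0.62 (double support), run 0.38 and
sprint 0.30 (flight phases) — and a stance shape `sin(πu) + dip·sin(3πu)`
(dip 0.25 in walking gives the classic two-peaked profile; 0 in
running/sprinting gives a single, higher peak). Peak scales are chosen in
closed form so the time-average of left+right equals body weight for any
duty factor. Measurement noise (8 N) is applied only while a plate is
loaded, so flight phases stay exactly zero; forces are clamped
non-negative. An optional cross-plate-strike fraction swaps left/right
assignment for a random subset of gait cycles, emulating a known artefact
of split-belt protocols (default 0).

### Sampling rates and seeding

Defaults: sEMG 1000 Hz, accelerometers 100 Hz, force plates 1000 Hz,
treadmill speed 300 Hz — all configurable. The speed rate is chosen
comfortably above twice the 50 Hz labelling filter cutoff so the filter is
realizable. One session seed fans out through a counter-based
`SeedSequence` scheme to the schedule, the speed noise and every channel in
canonical order, so sessions are bitwise-reproducible and each channel
independently so.

### What the generator does *not* emulate

No musculoskeletal dynamics, no motion-capture markers, no horizontal
force components, no electrode lift-off or day-to-day sEMG variability, no
fatigue drift, no real class imbalance beyond what lagged transitions
produce. Synthetic classes are cleaner and more separable than human data:
absolute accuracies here (≈95–99 %) exceed what the same pipeline achieves
on real recordings, and passing tests demonstrate that the *pipeline*
recovers planted structure — not that real-world accuracy would match.

## 2. Labelling

Activity labels are categorical and cannot be filtered, so the smoothing
prescribed for label stability is applied to the speed trace: a zero-phase
(forward–backward) 6th-order Butterworth low-pass at 50 Hz, followed by
thresholding. Zero-phase filtering avoids label lag; the effective
magnitude response is the squared single-pass response. "Speed = 0" for
standing is implemented as |v| < 0.05 m/s, since noisy or filtered speed
never equals exactly zero. Band upper bounds are inclusive. Window labels
are the majority label of the samples in [start, start + 0.5 s), ties
broken toward the label of the window's centre sample.

## 3. Features

Windows: 0.5 s, 0.30 s overlap (step 0.2 s), trailing partial windows
dropped; a 150 s trial yields 748 windows. Windows are half-open on the
right and each multi-rate stream contributes the samples that fall inside —
no resampling.

Per-window definitions and the decisions behind them:

- **ACC** — mean of per-sample Euclidean norms. "The vector norm of the
  accelerometer data in a window" is ambiguous (norm of the mean vs mean of
  norms); the mean of norms is robust to within-window oscillation and is
  used here.
- **FPM/FPSD** — sample mean and sample SD (n−1); single-sample SD defined
  as 0.
- **MF** — half-power frequency of a Hann periodogram (single periodogram
  per window, since 0.5 s windows are short; Welch averaging would only
  blur the few bins available), linearly interpolated between bins.
  All-zero windows map to 0 Hz.
- **H1/H2/H3** — fractions (not counts, so the features are
  sampling-rate-invariant) of samples at two-sided distances 0–1, 1–2, >2
  sample-SDs from the window mean; a zero-SD window is (1, 0, 0).

z-scoring is fit per training fold only and applied unchanged to held-out
data; per-trial normalisation (as used for the standalone PCA similarity
diagnostics) is also available. Fitting fails loudly on zero-variance
columns, naming the feature.

## 4. PCA similarity

PCA uses a full SVD; components are ordered by decreasing explained
variance with the sign convention that each loading column's
largest-magnitude entry is positive. Angles are computed *before* folding,
so the sign convention cannot hide genuine dissimilarity. Between two
models, the angle between components i and j is arccos of the loading dot
product (clamped to [−1, 1]); like-component angles (i = j) above 90° are
folded to 180°−θ. The angle matrix pools every unordered model pair with
equal weight (within- and cross-subject pairs are not distinguished; the
per-pair array is exposed for any weighting a user prefers) and reports the
median per entry, with the standard midpoint convention for even counts.

Diagnostics correlate PC1 scores with windowed mean treadmill speed and PC2
scores with the windowed left-minus-right plate force. The estimator is
Pearson's ρ (Spearman available by option); the absolute value per trial is
taken because component direction is arbitrary; median and IQR are reported
across trials.

## 5. Classification

Per subject, leave-one-trial-out: each of the six trials is held out once.
The normalizer and PCA come from the five training trials; the held-out
trial is projected with the training mean and loadings. The classifier is
an RBF-kernel SVM (scikit-learn SVC, natively one-vs-one) with C = 1 and
kernel scale from the median-pairwise-distance heuristic, γ = 1/(2s²),
with s the median Euclidean distance over a seeded subsample of at most
512 training scores (full pairwise distances on ~3700 rows would cost more
than the fit). These hyperparameters are declared defaults, exposed in
`SVMConfig`; no search is performed. k = min(3, n_features) components are
used, so two-feature ablation cases remain runnable. Folds whose training
data lack a class are skipped with a warning rather than failing the run.

Scoring: per-fold accuracy, raw (4 classes) and with run/sprint merged
(3 classes — merging can only convert errors into correct predictions, so
merged ≥ raw fold-wise); pooled confusion matrices; one-vs-rest sensitivity
and specificity per class, with empty denominators flagged as NaN rather
than coerced to 0; median and unscaled MAD across all subject × fold
accuracies.

## 6. Ablation

The eight canonical cases are immutable fixtures. Cases 1–6 retain every
feature family of each included combined sEMG+accelerometer unit (the
units are physically combined sensors, so their accelerometers travel with
them); Cases 7–8 are accelerometer-only. Force-plate features appear in
Cases 1, 4 and 5. The sources differ on Case 7/8 accelerometer counts; the
consistent reading adopted here is Case 7 = four accelerometers (one thigh
+ one shank per leg: vastus medialis and tibialis anterior, the defaults
being configurable) and Case 8 = two (the shanks). Feature counts per case:
44 / 20 / 20 / 24 / 24 / 10 / 4 / 2.

Effect sizes are Cohen's d with the pooled-SD denominator, computed on the
pooled subject × fold accuracy samples for both scoring regimes, with the
conventional magnitude labels (|d| < 0.2 negligible, < 0.5 small, < 0.8
medium, else large) and d(A,B) = −d(B,A). A zero pooled SD yields an
explicit undefined (NaN) rather than a number. Which sampling unit
(subjects or folds) underlies published effect-size tables of this kind is
generally unstated; fold-level samples are used here and the per-case,
per-subject results remain available in `AblationResult.case_results`.

## 7. Problem sizes and determinism

The default study (5 subjects × 6 × 150 s trials, 748 windows per trial)
simulates in ~15 s and the full eight-case ablation completes in ~35 s on
one CPU; the replicate analyses in the test suite run ten such studies.
Every entry point takes an integer seed and derives all internal randomness
from it via `numpy.random.SeedSequence`; identical inputs give identical
outputs, including the SVM (whose only stochastic element is the seeded
kernel-scale subsample).

## 8. Known limitations

- The sEMG surrogate has no motor-unit structure; median-frequency shifts
  are imposed, not emergent, so MF features are more informative here than
  in real recordings.
- Force plates carry no horizontal components and no centre-of-pressure
  drift; FPM/FPSD features are correspondingly clean.
- The run/sprint boundary is purely a speed threshold, as in the labelling
  scheme, so "sprint" has no distinct biomechanics beyond a shorter duty
  factor and higher peak force.
- Cross-subject angle comparisons assume the shared canonical feature
  ordering; studies with heterogeneous sensor layouts would need explicit
  alignment first.
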