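# Methods

## Problem and pipeline

Sheep spend most of their time budget grazing and ruminating; automatic
discrimination of grazing, ruminating and non-eating from a wearable IMU
(tri-axial accelerometer + gyroscope, 16 Hz, ear or collar mounted) enables
continuous welfare and intake monitoring without human observation. The
pipeline implemented here is: derived-channel construction → window
discretisation and labelling → 44-feature extraction → ReliefF feature
ranking → cross-validated learner comparison → confusion-matrix metrics.

## Channels and windowing

The tri-axial signals are reduced to magnitudes A̅ and G̅ (orientation
invariant) and their time derivatives AD, GD. The derivative is computed as
central differences on interior points and one-sided differences at the two
ends, scaled by the sampling rate, so all four channels stay index-aligned
and equal length — windowing then needs no per-channel bookkeeping. A raw
first difference would scale AD/GD by a constant 1/fs (rank-invariant for
almost all features) and shorten the channel by one sample; the
length-preserving scheme was preferred for alignment.

Windows are `round(window_s * fs)` samples (112 at the 7 s / 16 Hz
defaults) with hop `round(length * (1 - overlap))` (56 at 50 % overlap).
Trailing samples that cannot fill a complete window are dropped: windows
are required to be of equal length. A sample at time *t* is labelled by the
behaviour interval containing *t* under the half-open `[start, end)`
convention, which prevents double labelling at bout boundaries. A window
whose samples all share one label is *non-mixed*; otherwise it is flagged
mixed and assigned its predominant sample label, with ties broken by the
label of the window's first sample (deterministic and order-stable). Mixed
windows are kept in the modelling set with their majority label; a flag in
the evaluation config can exclude them.

## Feature characteristics

Eleven characteristics per channel × four channels = 44 features, named
`<stream>.<characteristic>`. Numerical conventions, fixed so results are
bit-for-bit reproducible:

- **std** is the sample (ddof = 1) standard deviation; **kurtosis** is the
  standardised fourth central moment m₄/m₂², with no excess-3 subtraction
  and no bias correction (any monotone variant preserves feature ranks;
  the simplest was chosen). Kurtosis of a constant window is undefined and
  reported as 0 with a warning.
- **iqr** is the 75th − 25th percentile with linear interpolation.
- **signal area** and **absolute signal area** are Σx·Δt and Σ|x|·Δt with
  Δt = 1/fs.
- **zero crossings** count strict sign changes of the *mean-centred*
  signal. The magnitude channels are non-negative, so crossings about raw
  zero would be identically 0 and the feature degenerate; centring is the
  only non-trivial reading. Samples exactly equal to the mean are treated
  as on the boundary and do not break a sign run.
- Spectral features use a plain one-sided periodogram (no taper) of the
  mean-removed signal, bin spacing fs/N, and exclude the DC bin.
  **Dominant frequency** is the frequency of the maximum-power bin (0 for
  a degenerate, zero-power spectrum; at 112 samples and 16 Hz the bins are
  multiples of 1/7 Hz, so a 2 Hz tone lands exactly on bin 14).
  **Spectral entropy** is the Shannon entropy in nats of the power
  distribution normalised to sum 1 (0 for a pure tone on an exact bin,
  ln K for a flat K-bin spectrum). **Spectral area** is the sum of the
  non-DC magnitude-spectrum bins times the bin width.

Two characteristic sets exist because the source material lists them both
ways: `table3` (default, includes spectral area) and `section25` (includes
absolute signal area instead). Either yields exactly 44 features.

## ReliefF

Multiclass ReliefF estimates feature quality by local contrast: for each
pivot instance R, its k nearest same-class neighbours (hits) pull the
weight of a feature down by the mean normalised difference, and the k
nearest neighbours of each other class C (misses) push it up, weighted by
the class prior P(C)/(1 − P(class(R))). Differences are normalised by the
global per-feature range, so weights lie in [−1, 1]. Choices the
algorithm's common description leaves open, fixed here:

- Manhattan distance on range-normalised features (the standard choice).
- Neighbour-distance ties break by instance index; the exhaustive variant
  (every instance a pivot, the default) is then fully deterministic and
  order-independent. Subsampled pivots (`n_sampled`) are seeded.
- The neighbour count defaults to k = 100, clipped per class with a
  warning when a class is smaller; zero-range features get weight 0 with
  a warning.
- Ranking sorts by descending weight with lexicographic tie-break on the
  feature name.

The implementation is validated against a naive all-pairs brute-force
recomputation to 1e-9 on toy problems.

## Evaluation harness

Stratified 10-fold cross-validation: folds preserve class proportions to
within one instance; each instance is predicted exactly once; the pooled
confusion matrix accumulates all held-out predictions, and its accuracy
equals the instance-weighted mean of per-fold accuracies. Learners are
scikit-learn implementations with conventional baseline hyperparameters
(surfaced in `CvConfig`): random forest with 500 trees; RBF SVM with C = 1
and training-fold standardisation; kNN with k = 5, distance-weighted;
AdaBoost with 100 depth-1 trees. Seeded learners make results reproducible.

The ReliefF ranking is computed once on the full dataset and reused across
folds by default, matching the sequential rank-then-validate procedure of
the comparison this package mirrors; `rerank_per_fold=True` re-ranks
inside each training fold for a strictly leakage-free estimate (slower,
statistically cleaner). The feature-count sweep reports the per-algorithm
maximum mean accuracy and its feature count, smallest count on ties
(favouring parsimonious, low-power models).

## Confusion-matrix metrics

Rows are observed behaviour, columns predicted. Per class: TP is the
diagonal cell, FN the rest of the row, FP the rest of the column, TN the
remainder; precision, recall, F-score (harmonic mean) and specificity
follow, plus overall accuracy = trace/total. All metrics are ratios of
cell sums, so matrices given in percent of the dataset (as published
summary tables are) behave identically to raw counts; percent inputs are
used as exact rationals with no attempt to recover integer counts. A
metric with a zero denominator is reported as absent (None), not 0 —
silent zeros would corrupt the macro averages, which are computed from
unrounded per-class values. Display rounding is round-half-up to integer
percent, matching the published tables' convention; full precision is kept
internally. The bundled collar confusion matrix reproduces its published
metric table under these conventions; the published non-eating specificity
(91 %) recomputes to 92 % from the printed matrix, and the ear-sensor
matrix is internally inconsistent with its stated overall accuracy, so
both are treated as orientation only.

## Synthetic data generator

Each behaviour bout contributes, per axis: a bout-constant orientation
offset (random unit vector times the regime's base magnitude), a sinusoid
at the regime's rhythm frequency along a random bout-constant direction,
and white Gaussian noise. The gyroscope carries the same oscillation/noise
structure scaled by `gyro_scale`, without the gravity-like offset. Bouts
are drawn uniformly from the configured length range (default 20–40 s,
long relative to the 7 s window) and follow shuffled round-robin triples,
so adjacent bouts always differ and the three classes stay roughly
balanced. Default regimes (arbitrary g-like units):

| behaviour  | base magnitude | rhythm (Hz) | amp  | noise sd | gyro scale |
|------------|----------------|-------------|------|----------|------------|
| ruminating | 0.9            | 1.0         | 0.15 | 0.05     | 0.5        |
| grazing    | 1.4            | 1.5         | 0.40 | 0.10     | 1.0        |
| non-eating | 2.1            | 3.0         | 0.20 | 0.35     | 0.7        |

These encode the qualitative structure reported for grazing sheep — mean
accelerometer magnitude ordered ruminating < grazing < non-eating, a
slower chewing rhythm for rumination than the biting rhythm of grazing,
and broadband higher-energy motion for non-eating activity — and make
magnitude, frequency and entropy features all behaviourally informative.
Ear placement only scales the gyroscope (more rotational than the collar);
no other asymmetry is modelled. The generator does **not** emulate
biomechanical detail, individual-animal variation, sensor drift or bias,
transitional movements, or label noise from manual video annotation.
Consequently the synthetic classes are far cleaner than field data:
near-perfect synthetic cross-validation accuracy demonstrates that the
pipeline's stages compose correctly, not that field accuracy would be
comparable.

## Problem sizes

The end-to-end synthetic run used by the tests and the acceptance script
is a two-hour trial (7,200 s, 115,200 samples, ~2,050 windows) — a
deliberately scaled-down analogue of a multi-day field experiment, chosen
as the smallest size at which all three classes comfortably exceed the
k = 100 ReliefF neighbourhood and 10-fold stratification. Toy oracle
checks use ≤ 60 instances where brute-force recomputation is exact and
fast.

## Known limitations

- ReliefF is O(n²) in windows (full distance matrix); fine to ~10⁴
  windows, beyond that pivot subsampling (`n_sampled`) is advised.
- Streams must be gap-free and uniformly sampled; no resampling or
  multi-rate support.
- No missing-value handling in ReliefF; no hyperparameter search in the
  evaluation harness; no per-axis features.
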