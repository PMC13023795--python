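# Methods

`ecgmi` implements a single-lead (Lead II) ECG classification pipeline for
myocardial-infarction (MI) detection: wavelet denoising, fixed-length
segmentation, hybrid DWT/EMD decomposition, time-domain + entropy feature
extraction, binary particle-swarm feature selection, and cross-validated
evaluation of four classifiers. This note records the model choices, the
defaults that matter, and what the synthetic experiments do and do not
show.

## Synthetic data model

Real MI-vs-healthy Lead II recordings (PTB-style, 1000 Hz, 16-bit) can be
ingested through the WFDB adapter, but the package is self-contained: a
template-based generator produces labeled records so every stage is
testable without downloads.

Each record is a sum of per-beat templates — Gaussian bumps for P
(0.15 mV, −220 ms from the R peak, σ 30 ms), Q (−0.08 mV), R (1.0 mV,
σ 11 ms), S (−0.15 mV) and T (0.35 mV, +320 ms, σ 50 ms) — placed by an RR
process with mean 850 ms and class-dependent Gaussian jitter, plus three
noise sources: a baseline-wander sinusoid (0.05 mV, 0.3 Hz), a powerline
sinusoid (0.02 mV, 50 Hz — European mains), and white noise.

Class structure, all configurable:

| parameter          | healthy | MI      | carried by                    |
|--------------------|---------|---------|-------------------------------|
| RR jitter SD (ms)  | 25      | 60      | rhythm irregularity           |
| ST offset (mV)     | 0.0     | +0.15   | amplitude features            |
| T-wave inversion   | never   | p = 0.5 per record | morphology         |
| white-noise SD (mV)| 0.030   | 0.045   | complexity/entropy features   |

The 1.5× white-noise ratio makes entropy features (not only amplitude
features) class-informative, reflecting the premise that pathology raises
signal complexity. The generator records its own beat landmarks (R
indices, ST measurement windows at +80..+150 ms from R, inside the
+65..+235 ms plateau), so tests can verify the constructed separation
directly. A template generator is deliberately simpler than a dynamical
ECG model: the downstream pipeline never uses beat annotations, so
quasi-periodicity with class-dependent ST/T/complexity differences is the
entire requirement. Effect sizes are package defaults, not estimates from
clinical data; passing tests demonstrate that the pipeline detects a
separation of this kind and magnitude, not clinical performance. MI mean
RR is kept at the healthy 850 ms — class signal lives in jitter, ST/T and
noise, not rate.

Determinism: `generate_record` is a pure function of its config (including
the seed); dataset seeds are `master_seed + record_index`.

## Preprocessing

Denoising is a six-level multilevel DWT with the Daubechies-6 wavelet,
periodization extension, soft universal thresholding of all detail bands:
threshold `σ √(2 ln N)` with `σ = median(|D1|)/0.6745`. The rule, mode and
a `threshold_scale` (0 = pure round-trip) are configurable.

Order of operations is denoise → min–max normalize → segment. The default
normalization scope is the whole record, in which case segments lie in
[0, 1] without necessarily attaining the bounds; per-segment scope (each
segment exactly spanning [0, 1]) is available via `norm_scope="segment"`.
Segments are non-overlapping 10,000-sample windows; the trailing remainder
is dropped. Constant inputs are rejected loudly — min–max scaling is
undefined there and a constant segment always indicates an upstream bug.

Periodization makes the multilevel DWT orthonormal, so coefficient energy
equals signal energy — exactly, however, only while every level's input
length is even. A 10,000-sample segment hits an odd length (625) at level
5, which perturbs energy conservation at the ~1e−6 relative level while
leaving perfect reconstruction intact. Energy tests therefore use the
nearest dyadic-compatible length (9984 = 156·2⁶); reconstruction tests use
10,000.

## Decomposition: 13 signal groups

Per segment: the original signal (`orj`), the DWT detail coefficients
`d1`…`d6` plus approximation `a6` (coefficient sequences, not
reconstructed band signals), and the first five intrinsic mode functions
`imf1`…`imf5` from EMD.

EMD uses classical sifting: strict local extrema (plateaus collapsed),
cubic-spline upper/lower envelopes with mirror extension of the two
outermost extrema past each boundary, mean-envelope subtraction, iterated
until a Cauchy criterion (relative change < 0.2) *and* the IMF
zero-crossing/extremum condition hold, capped at 100 iterations per IMF.
Inputs without oscillation return zero IMFs and the input as residue;
segments yielding fewer than five IMFs mark the remainder absent, and
their rows are dropped from experiments requiring the full feature vector.

Two properties are exact by construction and asserted: additivity
(ΣIMF + residue = input to 1e−9 of the amplitude) and, on clean
oscillatory mixtures, the IMF condition |#zero-crossings − #extrema| ≤ 1
on every accepted IMF. On denoised ECG composites the strict global count
can be violated by a few small-amplitude riding-wave extrema — forcing it
requires hundreds of sift iterations (heavy over-sifting) and does not
always converge, which is why practical EMD implementations stop on
energy-type criteria. We accept the candidate at the stopping rule and
assert the strict count only where sifting theory makes it exact.

## Features: 30 per component, 390 per segment

Seven time-domain statistics (min, max, mean, variance with n−1, RMS,
moment-ratio skewness, non-excess kurtosis; zero-variance series report
skewness = kurtosis = 0) and 23 entropy measures per component. The
literature lists these 22 named measures — attention, conditional
(corrected, 6-level quantization, m = 2), cosine-similarity (m = 2,
r = 0.1), distribution (m = 2, 64 distance bins), entropy-of-entropy
(window 5, 10 states), grid-distribution (3×3, lag 1), increment (m = 2,
resolution 4), phase (8 sectors), slope (m = 3, γ = 1, δ = 1e−3),
spectral (normalized periodogram), symbolic-dynamics (ternary quantile
alphabet, words of 3), Tsallis (q = 2), Rényi (α = 2), wavelet (db6
sub-band energies), Hurst (R/S), fuzzy (Gaussian membership
exp(−d²/2r²)), hierarchical multiscale, Kolmogorov–Sinai K2, multiscale
(Costa), permutation (order 3), enhanced multiscale (moving-average),
sample (m = 2, r = 0.2·SD) — and the registry is completed to 23 with the
16-bin amplitude-histogram Shannon entropy, which also anchors the
Rényi/Tsallis α→1 limits. The registry is order-stable and each entry can
be swapped or re-parameterized in one place.

Numerical conventions:

* tolerance r defaults to 0.2× the population SD of the analyzed series,
  making the template measures invariant under positive affine amplitude
  maps (asserted to 1e−9);
* all multiscale families evaluate scales 1–5 and return the mean over the
  scales at which the base entropy is defined, so every component
  contributes exactly one value per measure (30 per component holds);
  scales with no template matches are skipped rather than poisoning the
  mean — only an all-scales failure yields a missing value;
* estimators with O(n²) cost (sample, fuzzy, K2, cosine-similarity,
  distribution, and the multiscale families) evaluate the first 1000
  points of a component (`max_n`, configurable). 1000-point windows are a
  standard evaluation length for SampEn-type statistics; the estimates are
  stable there, while an uncapped 10,000-point evaluation would dominate
  the pipeline's runtime for no gain in class information;
* degenerate inputs (constant series for histogram measures, empty
  template sums) surface as logged missing values through the dispatcher;
  rows with missing values are excluded from experiments needing the full
  vector.

Feature naming is `<component>_<measure>` (e.g. `imf2_renyi`,
`d5_tsallis`, `orj_permutation`) in deterministic component-major order;
the full set is 390 columns, the DWT bands alone 210, the IMFs alone 150.

Sample, permutation, fuzzy, Rényi, Tsallis, distribution and increment
entropies are verified against independent brute-force enumerations
(double loops over templates, explicit pattern censuses) on short seeded
series — template counts exactly, values to 1e−12.

## Feature selection: binary PSO

Canonical velocity update v ← ωv + c1·r1·(pbest−x) + c2·r2·(gbest−x) with
fresh uniform r1, r2 per component, clamp ±6 (the sigmoid's saturation
range), sigmoid binarization (bit = 1 with probability 1/(1+e^−v)),
all-zero masks repaired with one random bit. Defaults: 30 particles, 100
iterations, c1 = c2 = 2, inertia 0.9 → 0.4 linearly.

Fitness (minimized): 0.99·(1 − innerAcc) + 0.01·(|mask|/N), where
innerAcc is stratified 5-fold CV accuracy of a k-NN (k = 5, per-fold
standardization) on the masked columns. The wrapper k-NN is a vectorized
numpy/scipy implementation — it runs ~10⁴ times per search and per-fit
library overhead would dominate; the report classifiers below are
independent of it, so selection and evaluation never share code. Fold
assignment is fixed once per search from the seed, so fitness is a
deterministic function of the mask and repeated masks are cached.

The selection benchmark plants 5 informative columns (class shift 2 noise
SDs) among 50; the generator defines ground truth, and recovery is
measured over 10 independently seeded searches of 20 particles × 40
iterations (recovery saturates well before that; the count keeps the
benchmark cheap enough to repeat ten times).

## Classification and metrics

Four classifiers with common Classification-Learner-style defaults, all
seeded: Bagged Trees (30 bootstrap trees, majority vote), SVM (RBF, C = 1,
kernel scale 1/#features), ANN (one hidden layer of 10 units,
backpropagation), k-NN (k = 5, Euclidean). SVM/ANN/kNN standardize with
train-fold statistics only; trees are scale-invariant and take raw
features.

Evaluation is stratified 10-fold CV with a shared fold assignment per
experiment; confusion counts are pooled across folds before computing
Acc, Rec, Spe, PPV and NPV (MI positive), reported as percentages to one
decimal. Pooling keeps the metrics well-defined with imbalanced folds, and
pooled accuracy equals the sample-weighted mean of per-fold accuracies (an
exact identity, asserted). Zero-denominator ratios are flagged missing
rather than silently zeroed. Class imbalance is handled by stratification
only — no resampling. CV is at segment level; records contribute multiple
segments, and grouping folds by record is available to the caller by
pre-assigning folds if patient-level leakage is a concern.

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` exercise the full pipeline on
50 + 50 (script) or 25 + 25 (tests) synthetic records of 20 s each — 200
and 100 segments of 10,000 samples with all 390 features. These sizes were
chosen as the package's standard desk-scale experiment; the structural
counts (13 groups, 30 features/group, 390 total) are invariant to them.
The label-permutation control reports the mean pooled accuracy over 5
independent label shuffles, since a single shuffle at n = 100–200 has a
sampling SD of several points.

## Known limitations

* The generator's morphology is schematic (Gaussian bumps); it contains no
  arrhythmias, no electrode artifacts, and a single lead. Results on it
  demonstrate pipeline correctness, not clinical accuracy.
* EMD boundary handling (mirror extension) and the sifting tolerance are
  fixed choices; IMFs are known to be sensitive to both.
* The strict IMF zero-crossing/extremum count is guaranteed only on clean
  oscillatory signals (see above).
* The Hilbert spectrum is not computed; the analytic signal appears only
  inside phase entropy.
* The WFDB adapter reads single-group format-16 records (the PTB layout)
  and nothing else; diagnostic labels must come from a caller manifest.
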