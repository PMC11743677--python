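# Methods

`eegmci` re-implements, as a tested library, a resting-state EEG
discriminant protocol for separating amnestic-MCI patients who progress
to Alzheimer's disease (PMCI, the positive class) from those who remain
stable (SMCI): preprocessing → spectral / nonlinear / connectivity
feature extraction → leakage-safe subject-level 10-fold cross-validated
classification.  This note documents the models, the parameter choices
made where the protocol leaves them open, and what the synthetic cohort
does and does not establish.

## Synthetic cohort model

No clinical recordings ship with the package; every downstream stage is
exercised on synthetic two-group cohorts (`eegmci.cohort`).  A subject's
16-channel, 500 Hz, 20-s recording is

```
x_c(t) = 30 µV · g_c · [ (1-ρ') b_c(t) + ρ' Re(z(t) e^{iφ_c}) + η w_c(t) ]
```

* `b_c` — unit-variance band-limited Gaussian noise whose per-band
  variances follow the group's relative band-power profile
  (delta/theta/alpha/beta/gamma weights summing to 1), with a 1/f
  in-band amplitude slope.  Band-limited noise is synthesised in the
  frequency domain (i.i.d. complex-Gaussian rFFT coefficients inside the
  band): this is distributionally identical to FIR-filtered white noise
  and makes Welch band powers directly controllable.
* `z` — one shared analytic alpha-band source (7.5–13.5 Hz) per subject,
  received by every channel with a fixed random phase offset `φ_c`
  uniform on the circle; `ρ' = 0.6 · connectivity_strength`.  Two
  deliberate choices here: (i) phases uniform on the full circle keep
  the channel-mean of the shared part near zero, so common-average
  re-referencing does not strip the source preferentially from the
  more-connected group; (ii) the source band is slightly wider than the
  8–13 Hz analysis band so its edges do not fall inside the alpha Welch
  bins and artificially notch the in-band spectral shape.
* `w_c` — flat-spectrum noise confined to 0.5–45 Hz with mixing weight
  `η = complexity_noise`, added *on top of* the unit-variance rhythms:
  more broadband noise means both more irregularity and slightly more
  in-band power, as in noisy EEG.  Confining it to the analysis band
  means preprocessing removes the same variance from every profile.
* `g_c` — per-channel gain in [0.8, 1.25]; absolute scale is irrelevant
  to every scale-free feature (ratios, entropies, connectivity) and
  enters only the phase-space spread statistic.

Group defaults emulate the clinical contrast: 65 SMCI vs 42 PMCI
subjects; the PMCI profile shifts relative power from alpha/beta toward
delta/theta ("high-to-low" slowing), and has lower coupling (0.30
vs 0.55) and lower complexity noise (0.30 vs 0.60).  The published study
reports only p-value topographies, not effect sizes, so the defaults
were calibrated once so that the cohort reproduces all the reported
group *directions* simultaneously (higher delta/alpha ratio, lower
alpha spectral entropy, lower sample/permutation entropy and phase-space
spread, weaker phase coupling in PMCI); they are not fitted to any
clinical dataset.  `CohortConfig.null()` (identical profiles) and
`CohortConfig.strong_effect()` (widened gaps) give the two reference
regimes used in validation.

Determinism: per-subject random streams derive from
`(cohort_seed, subject_index)` via NumPy seed sequences; identical
configurations regenerate cohorts bit-for-bit.

What the generator does **not** model: artifacts (blinks, EMG, line
transients), non-stationarity within a recording, volume-conduction
mixing beyond the shared source, realistic topographic gradients, and
1/f broadband slopes outside 0.5–45 Hz.  Passing tests therefore show
that the *pipeline* recovers differences of the kinds injected, not that
the features would behave identically on clinical EEG.

## Preprocessing

Order: common-average reference → zero-phase FIR band-pass 0.1–70 Hz →
zero-phase FIR 50 Hz notch (2 Hz wide) → polyphase down-sampling to
250 Hz → non-overlapping 2-s epochs (10 per 20-s recording; the trailing
remainder is dropped).  Filters are Hamming-windowed sincs applied
forward–backward through FFT convolution with repeated-reflection
padding; transition width is `min(max(0.25·f_low, 0.05 Hz), f_low)` at
the low edge and 25 % of the high edge, with kernel length capped at
twice the signal length (a 0.1 Hz edge on a 20-s segment cannot support
the nominal transition; the cap degrades it gracefully to ≈0.08 Hz).
An optional absolute-amplitude threshold drops epochs containing any
sample above it; component-based artifact removal is out of scope
(synthetic inputs are artifact-light) and `select_cleanest_window`
offers an automated stand-in for manual segment selection (the
contiguous window with the smallest peak amplitude).

## Features

All features are computed per 2-s, 250 Hz, 500-sample epoch (epoch mode)
or once per whole 20-s signal (subject mode).

**Spectral (200 per epoch).**  Welch PSD with 1-s Hamming windows, 50 %
overlap (2-s windows in subject mode).  Per channel: five band-power
ratios — δ/α, θ/α, δ/(α+β), θ/(α+β), (δ+θ)/(α+β+γ) — over half-open
bands δ[0.5,4) θ[4,8) α[8,13) β[13,30) γ[30,45); the Shannon entropy
(natural log) of the in-band PSD samples normalized to sum 1, per band;
and per homologous left–right pair, `log10 P_left − log10 P_right` per
band.  Zero-power degenerate cases yield NaN (missing), never ±∞.

**Nonlinear (528 per epoch).**  Per channel: multiscale permutation
(m=3, delay 1, stable-sort tie-breaking), approximate (m=2,
r=0.2·SD, self-matches included) and sample entropy (m=2, r=0.2·SD,
self-matches excluded, identical template counts at both lengths) over
coarse-graining scales 1–10 (non-overlapping block means), with the
AE/SE tolerance frozen from the scale-1 SD so scales are comparable;
Lempel–Ziv complexity (LZ76 exhaustive-history phrase count after
binarization at the mean, normalized by `n / log2 n`); the rescaled-range
Hurst exponent over dyadic block sizes 8…n/2; and the median Euclidean
distance of the 3-D delay-embedded trajectory from its centroid, with
the delay at the first non-positive autocorrelation lag (searched to
n/3, 1/e-crossing fallback, capped so at least one delay vector exists).
At scale 10 a 2-s epoch leaves 50 samples — marginal for sample entropy;
unmatched templates yield NaN for that scale only, handled downstream as
missing.  Parameters m, delay and r are protocol choices exposed as
arguments, not published values.

**Connectivity (2160 per epoch).**  All 120 channel pairs × 6 bands
(broadband 0.5–45 Hz plus the five bands) × three measures: Pearson
correlation of band-filtered signals; phase lag index
`|mean sign(sin Δφ)|` from the analytic signal of band-filtered data
with 5 % edge trimming; magnitude-squared coherence on the Welch
cross-spectral grid of the unfiltered epoch, averaged over in-band bins
(≥2 segments enforced — single-segment coherence is identically 1).
Matrices are symmetric with conventional diagonals (1, 0, 1) and are
vectorized as the strict upper triangle in channel order.

## Discrimination protocol

Rows (epochs or subjects) are split by **subject** into 10 stratified
folds — no subject's epochs ever appear on both sides of a split.
Within each fold, using training rows only: (1) a feature is retained
when its Welch t-test *or* Wilcoxon rank-sum p-value is below α = 0.05
(the protocol names both tests without stating the combination; the
inclusive either-rule is the default and a both-rule is available —
PCA later absorbs redundancy); constant features are always dropped;
(2) missing values are imputed with training-fold medians, features are
z-scored with training means/SDs, and PCA (SVD on the standardized
block) keeps the smallest number of components reaching 95 % cumulative
explained variance, with the sign convention that each component's
largest-magnitude loading is positive.  The held-out rows pass through
the stored transform unchanged.  Eight scikit-learn classifiers run
with library defaults (SVM-RBF, decision tree, Gaussian naive Bayes,
LDA, AdaBoost, KNN, random forest, logistic regression), seeded where
stochastic.  Metrics per fold: confusion counts with PMCI positive,
ACC/SEN/SPE/PPV/F1, and the rank-based AUC
`(Σ ranks of positives − M(M+1)/2)/(M·N)` with average ranks for ties
(the Mann–Whitney estimator); folds are summarized as mean ± SD, not
pooled.  Degenerate ratios (zero denominators) are NaN, and a fold with
a single-class test set leaves the class-conditional metrics missing
without aborting the run.

A caveat reproduced faithfully from the protocol: epoch-level univariate
selection treats rows as independent although epochs cluster within
subjects, so under the null it retains ~12 % of features at α = 0.05
rather than ~6 %.  This inflates selection, not evaluation — folds are
subject-level — and is why the null-calibration checks of the package
measure chance-level AUC on held-out subjects rather than the selection
rate on clustered rows.

## Cohort statistics and group maps

`cohort_statistics` reproduces demographics-table tests from printed
summaries: pooled-variance two-sample t for (mean, SD, n) pairs and
Pearson χ² without continuity correction for contingency counts —
the conventions that reproduce the published table values.
`group_difference_map` screens any feature family with Wilcoxon
rank-sum tests and organizes p-values by channel or channel pair
(a tabular p-value topography), with a top-n listing for connectivity
edges.

## Validation design and problem sizes

The published headline classification numbers come from non-deposited
clinical EEG and are not reproducible targets; validation instead rests
on (a) printed, recomputable statistics (the demographics table), (b)
exact oracle equivalence — every nonlinear statistic and the rank-AUC
match independent brute-force reimplementations to 1e-10 on dozens of
random inputs — plus closed-form identities, and (c) end-to-end
behaviour on synthetic cohorts: chance-level AUC for all eight
classifiers on a default-size null cohort (the default size keeps ~11
test subjects per fold, bounding the Monte-Carlo spread of fold AUCs),
near-perfect KNN AUC plus all six group directions on a strong-effect
cohort (16+16 subjects, entropy scales 1–3), and an explicit leakage
audit (corrupting held-out rows must not change any fitted transform).
`scripts/acceptance.py --seed S --out results/acceptance.json`
recomputes all of these from scratch.

## Known limitations

* EDF export is a minimal 16-bit encoder (1-s records, per-channel
  symmetric physical scaling); reading uses MNE.  EDF+ annotations are
  not supported.
* Hurst estimation is classical R/S; detrended methods are out of scope.
* No hyperparameter tuning, nested CV, feature-importance ranking or
  graph-theoretic connectivity summaries.
* Subject-mode nonlinear features on 5000-sample signals are
  quadratic-time; the entropy internals are chunked to bound memory, but
  large subject-mode runs are best restricted to the spectral and
  connectivity families.
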