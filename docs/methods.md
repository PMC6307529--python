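# Methods

This note documents the models implemented in `ptebio`, the defaults and why
they were chosen, what the simulators do and do not emulate, and the
numerical decisions a maintainer should know about.

## EEG windowing and the local-Mahalanobis metric

A recording (microvolts, `fs` samples/second) is cut into windows of
`window_size` samples with fixed 50% overlap; the trailing remainder is
dropped, so `n_segments = (n_samples − window_size) // (window_size/2) + 1`.
The default window is 400 samples (2 s at the 200 samples/second rate
typical of long-term scalp recordings): long enough to estimate a stable
channel covariance, short enough to isolate individual spike-wave complexes.

Each window `i` is summarized by its per-channel mean vector `μᵢ` and its
channel covariance `Σᵢ` (time-based covariance across the window). The
dissimilarity between windows is the quadratic form

    d(i, j) = (μⱼ − μᵢ)ᵀ · ½(Σᵢ⁺ + Σⱼ⁺) · (μⱼ − μᵢ)

with `Σ⁺` the SVD pseudo-inverse (singular values below `svd_tol · σ_max`
zeroed; `svd_tol = 1e−6` by default, the usual float64 working precision for
covariances of this size). Averaging the two windows' inverse covariances is
the symmetrized local-covariance Mahalanobis construction used in
covariance-based signal denoising; it makes `d` symmetric by construction.
A flat (all-zero-covariance) window gets a zero pseudo-inverse and
contributes zero distance, with a logged warning. The quadratic form is the
squared-distance scale — no square root is taken — and is computed for all
pairs (the kernel needs a full matrix); the consecutive-window values are
also reported separately since they are the natural scan statistic.

Note a consequence of using mean features: the metric sees baseline shifts,
not waveform shape. Purely zero-mean transients are invisible to it, which
is why the simulator's spike morphology carries net area (see below).

## Affinity kernel and its scale

The affinity is `A = exp(−d / (4 kₑ))` elementwise. `kₑ` defaults to the
literature value 10, which was chosen for raw-EEG distance scales; under the
whitened metric above, distances are O(0.01–1) and a fixed 10 makes the
kernel nearly flat — every non-leading eigenvalue of the (twice-squared)
operator collapses toward numerical zero and embedding selection degenerates
into picking noise directions. Because the scale is meant to track the
spread of the data, the package provides `k_e="median"`: set
`4kₑ = median(off-diagonal d)`, i.e. the median pairwise distance maps to
affinity `e⁻¹`. This is the standard median bandwidth heuristic for Gaussian
kernels and is the recommended setting (and the one used by the simulation
tests); the numeric default stays 10 for continuity.

## Two-stage normalization and spectral embedding

With `j₁` the row sums of `A`, stage one forms the symmetric normalization
`A₁ = D₁^{−1/2} A D₁^{−1/2}` (`D₁ = diag j₁`) and squares it: `W₁ = A₁²`.
Stage two repeats this on `W₁` (row sums `j₂`) giving `A₂` and `W₂ = A₂²`.
`W₂` is symmetric positive semidefinite; its spectrum lies in [0, 1] and its
leading eigenvalue is exactly 1 with eigenvector `√j₂` (both facts are
asserted by tests). Eigenpairs are sorted descending and the point-cloud
coordinates are `V_clds = diag(j₂^{−1/2}) · V`, so the leading column is
constant and each remaining column is a diffusion coordinate of the two-step
squared random walk. Eigenvector signs are fixed deterministically (largest-
magnitude entry positive), making the whole pipeline bitwise reproducible.

The squaring stages compress the spectrum steeply (an eigenvalue λ of the
underlying chain appears as ≈ λ⁴), which is another reason a well-scaled
kernel matters: structure must enter with λ near 1 to survive.

## Nyström extension

A held-out window's raw affinity row `b` to the training windows is pushed
through the same two stages: normalize by `√(Σb · j₁)`, multiply by `A₁` to
get its `W₁` row, renormalize, multiply by `A₂`, and project on the
orthonormal eigenvectors with division by the eigenvalue. Because this uses
the eigenvectors of `W₂` itself (not of `A₂`), extending an in-sample row
reproduces its point-cloud coordinates to working precision regardless of
near-degenerate eigenvalue pairs; the test suite requires 1e−6 relative
agreement. Rows with zero affinity to the training set are rejected by name.

## Embedding selection and outlier flags

All `C(n_eig − 1, 3)` triples of non-trivial eigenvectors are candidate 3-D
embeddings (the constant leading eigenvector is excluded). Each candidate's
spread is the mean Euclidean distance of its points to their center of mass;
the maximal-spread triple wins, with ties broken to the lexicographically
smallest triple for determinism. Because coordinates are scaled by
`j₂^{−1/2}`, weakly connected (anomalous) windows inflate the spread of the
eigenvectors that localize on them, which is what lets this criterion find
outlier-bearing embeddings.

Outlier scores are distances to the embedding's center of mass. Two flagging
rules: `mad` (score > median + param · MAD, default param 3 — a robust
z-score) and `quantile` (top `round(param · n)` scores, default 5%). Flags
map back to window start times.

Retaining `n_eigenvectors = 8` balances candidate-triple diversity
(C(7,3) = 35 candidates) against the spectral compression noted above.

## Mutual information

The estimator is the plug-in joint-histogram MI with `n_bins = 16`
equal-width bins per axis spanning each window's observed range, reported in
bits. It is deterministic, non-negative, exactly symmetric (marginals are
taken from integer counts and the sum uses order-independent compensated
summation), invariant under monotone affine rescaling of either input, and
exactly zero for constant inputs. Its positive bias is ≈ (B−1)²/(2N ln 2)
bits (≈ 0.027 bits for 30 s windows at 200 samples/second), a constant
offset that cancels in trend statistics. Windows are consecutive and
non-overlapping (default 30 s) with the trailing partial window dropped.
The trend over windows is summarized by the OLS slope (bits/window) and a
two-sided Spearman rank test; 16 bins keeps the bias ≪ the coupling-driven
MI range while resolving moderate dependence.

## Spectral analysis

`stft_spectrogram` computes a one-sided PSD (µV²/Hz) per frame on the raw
signal (per-frame mean removal only), default 1 s hann frames with 50%
overlap — standard EEG practice, matching the windowing idiom used
elsewhere in the package; a rect taper is available and makes the Parseval
check exact to within spectral leakage (tests require 5%). `band_power_series`
integrates the PSD over a band with the trapezoid rule; `threshold_events`
extracts maximal half-open intervals above a threshold, discarding those
shorter than `min_duration_s`.

## EEG simulator: what it emulates, and what it does not

Defaults (the study conditions asserted by the tests): 5 channels,
200 samples/second, 300 s; 1/f background with 15 µV SD per channel behind a
0.5 Hz second-order high-pass (the acquisition front-end of clinical EEG —
without it, sub-hertz drift dominates window means); spike-wave complexes at
0.05/s with 150 µV amplitude, 70 ms sharp phase plus a same-polarity slow
wave (the classic surface-negative spike-and-wave morphology, which gives
the transient net area and hence a baseline signature visible to the
mean-feature metric); a focal spatial topography (exponential gain fall-off
from a focus channel) with ±10 ms per-channel latency jitter; and a shared
latent signal whose mixing fraction ramps linearly (default 0.05 → 0.6;
trend experiments use 0 → 0.8) up to the seizure onset, producing the rising
inter-channel MI signature. One integer seed fans out to per-component
substreams, so enabling or disabling one component never perturbs another.

Not emulated: realistic electrode geometry or volume conduction, artifacts
(movement, EMG, electrode pops), non-stationary background rhythms, and any
biophysical seizure dynamics — the "seizure" is only a coupling ramp.
Passing tests therefore demonstrate the algorithms' behavior under their
intended signal model, not clinical detection performance.

## PVS simulator and asymmetry statistics

Per subject, a total count is drawn as round(N(count_scale = 78,
count_sd = 30)) (floored at 10); an asymmetry index is drawn from
Gamma(shape 2, mean = group target — 0.17 TBI-like, 0.04 control-like),
capped at 0.95; the majority side is random and the split is
`major = round(total · (0.5 + AI/2))`. Drawing AI directly and splitting
deterministically (rather than drawing counts binomially) keeps the group
mean on target: a binomial split would fold sampling noise into |AI| and
bias small targets upward by ~0.09 at these counts. Calibers are
N(1.35, 0.22) mm, clipped to the measurable [0.5, 3.0) mm range, with the
minor hemisphere's mean lowered by `slope · AI` (slope 0.5 mm) — the
smaller-PVS-on-the-injured-side effect — so AI and |C_diff| are positively
related by construction. Ages are uniform on 7–68 years.

Analysis conventions: HR pairs always sum to 1; an exact count tie gives
HR_minor = HR_major = 0.5 and AI = 0. Grading is high for AI ≥ 0.2
(equivalently, one hemisphere above 60% of the total), with boundary
inclusion honored to within 1e−12 to absorb float representation of count
ratios. The intermediate band 0.1 ≤ AI < 0.2 is a package convention (the
literature defines only the high threshold); both thresholds are
parameters. Group comparisons default to the classical equal-variance
Student t-test with a Welch variant behind a flag; correlations are Pearson
with two-sided t-based p-values. Subjects with zero in-range markers are
excluded from grading with an explicit report rather than assigned an AI;
caliber loading drops markers outside [0.5, 3.0) mm (half-open: 0.5 kept,
3.0 excluded) and counts them in the load report.

## File formats

EDF (16-bit) is the canonical EEG container; reading goes through `mne`,
and the package ships its own standards-conforming writer (one data record
spanning the signal, integer microvolt physical limits rounded outward, so
quantization error is ≤ range/65535). EDF cannot represent non-finite
samples, so the writer rejects NaN/inf naming the offending channel and the
reader applies the same gate after load. The `csv_matrix` dialect (header
of channel labels, one row of samples per channel, JSON side-car with
`fs`) exists so fixtures stay human-readable. PVS marker tables are CSV
with one marker per row (`subject_id, group, age, sex, hemisphere,
caliber_mm`); per-subject metadata must be consistent across rows.

## Problem sizes used in the test suite

The simulation-backed tests run at the defaults above: 300 s × 5 channels
for spike detection (299 windows), 100 seeds × 300 s × 2 analysis channels
for the MI trend and its null control, and 50 seeds × 21 subjects for the
PVS recovery — sizes chosen so each property is measured at the same
conditions the generators define while the whole suite stays fast.

## Known limitations

* The mean-feature Mahalanobis metric cannot detect zero-net-area
  transients or pure variance changes between windows; a waveform-level
  metric would, at higher cost.
* With the historical `k_e = 10` on whitened distances the embedding is
  numerically degenerate (see above); use `k_e="median"` for data whose
  distance scale is unknown.
* The spectrum compression of the two squaring stages limits how many
  eigenvectors carry signal; requesting many eigenvectors mostly adds
  numerically null directions.
* The per-subject caliber t-test treats markers as independent samples;
  spatial correlation between neighboring PVSs is not modeled.
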