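# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a methods appendix.

## Stimulus model

**Spectrally matched noise.** The noise partner of an image is produced
in the 2-D Fourier domain: amplitudes are kept bin-for-bin, phases of
all non-self-conjugate frequency pairs are replaced by i.i.d. uniform
draws on [0, 2π) with Hermitian symmetry enforced, and the
self-conjugate bins (DC, and the Nyquist corners of even-sided images)
keep their original real values. This preserves the amplitude spectrum
to machine precision and the image mean exactly, and guarantees a real
output. Phase randomization happens at the image's native resolution,
before any downsampling; the alternative order is not exposed because
randomizing after downsampling would let the anti-aliasing filter see
phase-dependent structure.

**Downsampling** is repeated 2×2 block averaging (factors are powers of
two). Block averaging is mean-preserving and anti-aliasing; strided
subsampling is available via `method="stride"` for comparison. The
nominal factor of 4 maps a 256 px stimulus to 64 px so that a
second-stage receptive field of 39 px covers a similar stimulus fraction
as a typical V2 receptive field.

**Contrast normalization** maps an image affinely to a target mean β
(default 0.5) and target standard deviation α (default 0.22). The
*population* (divide-by-N) standard deviation is used so the
postcondition is exact for any image size; the map is idempotent at its
fixed point. Out-of-range pixel values are not clipped — the feature
model accepts real-valued inputs, and clipping would break the affine
contract.

## Synthetic texture families

The generator stands in for iterative joint-statistic-matching texture
synthesis, keeping only the property the analysis depends on: texture
and noise partners share the amplitude spectrum exactly and differ in
higher-order statistics. Each family owns a reference amplitude
spectrum (1/f radial falloff plus an oriented band-pass lobe, peak
frequency 0.08–0.2 cycles/px) and a sparseness threshold drawn once per
family. A sample is built from white noise by imposing the family
spectrum, applying a pointwise nonlinearity (sign-preserving squaring
followed by soft thresholding, threshold ~ U(0.5, 1.5)), and flattening
the spectrum back to the family reference. The nonlinearity concentrates
energy into sparse oriented features; empirically it raises the
kurtosis of oriented-filter outputs by several units relative to the
phase-randomized partner, while `structure_strength = 0` yields exactly
a Gaussian process with the same spectrum. Sample randomness is keyed
by `(seed, family, sample)` named substreams, so enlarging a family
never changes existing samples.

What the generator does **not** emulate: matched marginal pixel
statistics across families, cross-scale statistics of natural photos,
long-range structure beyond the filter scale, and the perceptual
diversity of real texture ensembles. Passing tests therefore certify
the pipeline's mechanics and its sensitivity to planted higher-order
structure, not performance on any specific natural texture set.

## Planted response tensors

For parameter-recovery tests, model-neuron responses are generated with
an exactly known modulation matrix: per (neuron, family), texture and
noise means are T(1+m)/2 and T(1−m)/2 with T a positive random total,
so the family-mean index is m exactly at zero jitter. Per-sample jitter
is Gaussian, truncated at zero (responses are post-rectification, hence
nonnegative); truncation rather than resampling keeps the generator a
pure elementwise function of its random draws. The truncation biases
means upward slightly when T(1±m)/2 is within ~2 SD of zero — relevant
only at |m| near 1 combined with large `noise_sd`.

## Feature model

Layers are convolution (cross-correlation with zero padding),
rectification, overlapping max pooling, and local response
normalization (LRN). LRN divides each rectified activation by
`(k + α Σ a²)^β`, the sum running over a depth window of `m` channels
clamped at channel edges; defaults k = 2, α = 1e−4, β = 0.75, m = 5.
The default layer order applies normalization *after* pooling
(CaffeNet convention). Receptive-field sides follow the standard
recursion `rf ← rf + (window − 1)·jump, jump ← jump·stride` over conv
and pool layers; padding affects map sizes but not the RF side. Bundled
geometries: the AlexNet variant with conv1 stride 2 (RF 15 px at pool1,
39 px at pool2), the standard stride-4 front end (67 px at pool2), and
VGG16 (6/16/44 px at pools 1–3).

Weight modes: `provided`, `random` (i.i.d. uniform on [−1, 1]) and
`shuffled` (per-filter spatial permutation, independently per input
channel; cross-channel shuffling is available behind a flag since
"spatial" shuffling is ambiguous about channels). Grayscale stimuli are
replicated across input channels when a spec declares three, the
conventional choice for feeding grayscale stimuli to an RGB-shaped
front end.

Populations are (filter, spatial position) units: a chosen filter subset
times a centered s×s neighborhood of the tap-point map (default 2×2),
ordered filter-major then row then column.

## Modulation indices

Family responses are averaged over samples *before* the index is
formed; this stabilizes the ratio and keeps the index defined whenever
the summed family response is positive. (Averaging per-sample indices
instead is available behind `per_sample=True`; with finite samples the
two orders differ, and the ratio-of-means is the variant whose planted
recovery is exact.) A neuron is invalid if `r_na + r_no ≤ 0` for any
family — the exact condition under which the index is undefined — and
invalid neurons are flagged, not raised, then excluded from fits.

The permutation null band shuffles texture/noise labels within each
(neuron, family) cell across samples and recomputes the valid-neuron
mean modulation per family; the 2.5th/97.5th percentiles over
permutations form the band. The choice of null is ours: the analysis
needs "no texture/noise asymmetry" while preserving each cell's
response distribution, which label exchange achieves directly.

## Fitting procedures

Greedy forward selection evaluates, at step j, every unselected valid
neuron's effect on the equally weighted mean of j rows and keeps the
minimizer of the squared Euclidean distance to the target; ties break
toward the lowest neuron index for determinism. Greedy error is not
monotone in k (the equal-weight mean can worsen); only the first step
is guaranteed optimal among single rows.

The simplex-constrained least-squares problems (plain and ridge-
regularized) are solved by accelerated projected gradient (FISTA with
adaptive restart) using exact Euclidean projection onto the probability
simplex; iteration stops when the projected-gradient residual falls
below 1e−9, i.e. the KKT conditions hold to that tolerance. Tests
verify the solutions against dense simplex grid searches. The
regularized method reports the fraction of weights above 2e−3 (default)
and selects the k largest-weight neurons, ties again toward lower
indices, re-scoring them as an equally weighted average — matching how
a recorded population's index is computed. Default λ = 0.8; default
k = 103 (102 for first-layer populations), the recorded-population
sizes this analysis is built around. When more than k weights exceed
the threshold, top-k by weight is the selection rule.

## Cross-validation

Leave-one-group-out: each family's samples are partitioned at random
into groups (nominally 15 images), each (family, group) is one data
point, and each fold refits the selection with one point held out,
predicting that point's population mean modulation from the held-out
samples alone. Folds with undefined held-out indices are skipped with a
warning and excluded from aggregates rather than imputed. The aggregate
test error is the Euclidean distance between per-family mean
predictions and the target. Leave-family-out fits on all-but-one
family's columns and predicts the held-out family as the fitted
population's (weighted) mean of that family's column — the natural
predictor given that the fit carries no other information about the
held-out family.

## The trained-versus-random comparison

`cv_evaluation.structured_vs_random_replicate` compares a two-stage
model whose second stage is built to detect texture structure against
the same model with uniform random second-stage weights. The first
stage is a signed Gabor bank (8 orientations × 2 frequencies ×
quadrature phases and both signs, so rectified pairs carry full-wave
energy). The structured second stage consists of energy-coincidence
detectors: center excitation across all of one orientation's channels
with balancing surround inhibition (gain 1.4 over a 5×5 kernel) — a
unit fires when oriented energy across phases and scales coincides at
one location above its local background, the signature of aligned phase
structure that spectrally matched noise lacks. The target vector is the
mean modulation profile of the structured model probed with
*independent* samples of the same families, standing in for data
recorded from a texture-sensitive neural population, and fit errors are
evaluated on held-out samples so sample-noise diversity cannot
masquerade as fit quality. Replicates use 10 families × 6 samples at
36 px with k = 30 — problem sizes chosen to keep a 100-replicate run in
the minutes range while leaving the effect unambiguous (structured mean
modulation ≈ +0.3 versus ≈ 0 for random weights in pilot runs).

## Known limitations

* The feature model is CPU/NumPy; it is meant for desk-scale analyses
  (tens of filters, ≤ 100 px stimuli), not ImageNet-scale networks.
  Real pretrained weights can be supplied via `WeightSet.load` but are
  never required.
* Convolution groups (the split-GPU channel topology of the original
  AlexNet) are not modeled; bundled specs use full channel connectivity.
* The regularized method's ridge favors populations with shared
  structure; on profiles that are independent noise its top-k selection
  approaches a random draw (see the README example).
* `explained_variance` is undefined for zero-variance targets and can
  be strongly negative when the target's variance is small relative to
  the fit residual; it is reported alongside, never instead of, the
  Euclidean error.
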