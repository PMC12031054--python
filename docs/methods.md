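# Methods

This note records the modelling choices behind `leafspad`, the
assumptions they rest on, and what the synthetic benchmark does and does
not demonstrate.

## Imaging model and segmentation

The package assumes light-box photography: one leaf, white paper
background, even illumination. Under these conditions background pixels
are high-value and low-saturation in HSV while leaf pixels — green
through yellow-brown — are saturated. Segmentation therefore thresholds
saturation ≥ `s_min` (default 0.15) and value ≤ `v_max` (default 0.98),
labels 8-connected components, keeps the largest (ties broken by the
first pixel in row-major order), and fills its holes so veins and
specular spots stay inside the region of interest. An optional hue gate
exists but is **off by default**: chlorotic leaves can drift below 40°
hue (red-dominant), and a default-on green gate would reject exactly the
low-chlorophyll leaves the method is most useful for. The hue convention
is degrees in [0, 360); users of 8-bit 0–179 conventions must scale.

The median filter (default kernel 5, must be odd) is applied per channel
over the full image and composited inside the mask only. Windows that
straddle the leaf boundary therefore see some background; this affects
only a one-or-two-pixel rim and is negligible against ROI areas of 10³
pixels and up. Tests pin the interior behaviour exactly and tolerate the
rim.

## Color indices

All 28 indices are evaluated on the ROI channel means — one vector per
leaf — not per-pixel and then averaged. The channel means are computed
first and every index is an algebraic function of those three scalars,
which keeps the indices well-defined, cheap, and independent of leaf
area. Normalisation is the standard chromaticity r = R/(R+G+B) (likewise
g, b). A zero denominator (pure black ROI and similar pathologies)
yields NaN — flagged and propagated, never silently replaced — and such
samples are dropped from correlation/PCA fitting. For any real leaf
photograph all denominators are comfortably positive.

## Screening and PCA

Feature screening is Pearson correlation against SPAD with two modes:
a fixed canonical list of 21 indices (default), or all indices with
|r| ≥ 0.7. The list mode exists because strongly collinear index
families make a uniform cutoff unstable across datasets.

PCA operates on standardised features, i.e. on the correlation matrix.
The index families live on wildly different scales (raw channels ~10²,
ratios ~1), so covariance PCA would be dominated by the raw channels.
Five components are retained by default (`k_fixed=5`); a cumulative
variance target is available instead. Loading signs are fixed so the
largest-magnitude element of each component is positive, making scores
byte-stable across runs; ties in eigenvalues are broken by descending
eigenvalue order as returned by the (deterministic) full SVD.

## SVR

The ε-insensitive SVR is solved by libsvm via scikit-learn behind the
package's own model object (support vectors, dual coefficients, bias —
serialisable to JSON). Defaults: linear kernel, C = 10, ε = 0.1. ε is
small relative to the SPAD standard deviation (~6) emulated by the
generator. A widely circulated configuration for this task — linear
kernel with C = 0.01 and γ = 150 — is expressible, but note that γ is
mathematically inert for a linear kernel (the fitter stores it and warns)
and C = 0.01 regularises the model down to a near-mean predictor on
component-score inputs; it is not the default for that reason. The
solver iteration count is capped at 10⁶ because near-interpolating
configurations (huge C, tiny ε) otherwise chase the last 1e-9 of duality
gap indefinitely.

## RVM

The relevance vector machine is implemented from scratch (no maintained
scikit-learn implementation exists): a sparse Bayesian linear model over
kernel basis functions — one per training sample plus an always-included
bias column — with an independent Gaussian prior of precision αᵢ on each
weight and noise variance σ². Hyperparameters are driven by type-II
maximum likelihood with the classical fixed-point sweeps:

    Σ = (σ⁻² ΦᵀΦ + diag(α))⁻¹        μ = σ⁻² Σ Φᵀ y
    γᵢ = 1 − αᵢ Σᵢᵢ                   αᵢ ← γᵢ / μᵢ²
    σ² ← ‖y − Φμ‖² / (n − Σγᵢ)

Basis functions with α > 10⁹ are pruned each sweep; iteration stops when
max |Δ log α| < 10⁻⁶ or after 3000 sweeps. Initialisation is
deterministic (αᵢ = 1, σ² = 0.1·var(y)); there is no randomness in the
fit. A 10⁻¹² jitter stabilises the posterior solve when near-duplicate
basis columns survive. Predictions return mean Φ\*μ and variance
σ² + φ(x\*)ᵀΣφ(x\*); far from all relevance vectors the variance tends
to σ² plus the bias-weight uncertainty. Freezing α and σ² (and thereby
disabling pruning) reduces the fit to dense Bayesian ridge regression,
which the tests exploit as a closed-form cross-check. Kernels: linear,
or Gaussian exp(−γ‖x−x′‖²) with γ = 0.01 by default standalone and
γ = 0.05 as the hybrid head.

## CNN

The network treats the 5-vector of component scores as a single-channel
1-D sequence. Blocks are convolution ("same" padding: left (k−1)/2,
right k/2) → batch normalisation → ReLU → max-pool (window 2, stride 2,
odd tail dropped); lengths run 5 → 2 → 1 through two blocks. The
standalone model uses one block of 16 filters; hybrids use two blocks
(16, then 32) so that a "pool2" layer exists to tap (32 activations).
The head is flatten → dense(32) → ReLU → dense(1); there is no canonical
head size for so small a network, so the minimal two-layer head was
fixed once. Everything is NumPy with hand-derived backprop, verified against
central finite differences in the test suite.

Training: full batch (n ≤ ~500 makes mini-batching an unnecessary
hyperparameter), Adam (β = 0.9/0.999), initial learning rate 0.01 with a
×0.1 staircase every 100 epochs, L2 penalty 0.001·Σ‖W‖² on convolution
and dense weights, global gradient-norm clipping at 1.0 (the post-clip
norm is logged every epoch), up to 1000 epochs with early stopping at
patience 10 on a validation loss, best-validation weights restored.
Weight init is seeded He-uniform; a fixed seed reproduces logs and
weights bit for bit.

One design choice needs calling out: the output layer is composed with a
fixed affine map, prediction = raw·sd(y) + mean(y), anchored at the
training-target statistics (gradients flow through the scale). Targets
on the SPAD scale sit near 42, and with clipped, lr-bounded updates a
zero-initialised network would spend thousands of epochs just moving its
output bias there. The anchor makes the untrained network the mean
predictor, which is the natural origin for a regression net. It is an
architectural constant, not a trained parameter, and is serialised with
the weights.

Hybrid training is staged: the CNN is trained on (X, y) with early
stopping, frozen, its tap-layer activations are extracted for all
training rows, and the SVR/RVM head is fitted on those features against
the same targets. Prediction composes the frozen extractor with the
head. The tap defaults to the last pooling layer ("pool2").

## Evaluation protocol

The 80/20 split draws a seeded permutation with |validation| =
round(0.2·n); 5-fold cross-validation partitions a seeded permutation
into near-equal folds, every sample validating exactly once. All models
inside one report share the identical fold assignment. By default the
screening and PCA are refitted inside each training fold, so no
validation information reaches the transform; `pooled_preprocessing=True`
reproduces the historical fit-once-on-all-data ordering for comparison,
with the leak that implies. Reported SDs are across the 5 folds
(ddof = 1). The default split/fold seed is 20240625.

## Synthetic data: what it emulates and what it does not

The generator emulates light-box acquisition: an elliptical leaf
(semi-major 30–42% of the short side, eccentricity and rotation random,
optional 10%-darker midrib stripe) over a near-white background
(250 ± 3 per channel). SPAD values are truncated-normal — mean 42.05,
SD 5.99, bounds [21.90, 55.90], matching the summary statistics of the
field campaign being emulated — and the mean leaf color responds
linearly to the standardised SPAD value s̃:

    (R, G, B) = (90 − 25·s̃, 130 + 10·s̃, 60 + 8·s̃),  noise SD 4/pixel

The signs encode the physiology: more chlorophyll → greener/bluer, less
red dominance. The coefficients were chosen once so that every color
stays strictly inside [0, 255] over the SPAD range and the anchor
indices ((G+B−R)/(2G) rising, R−B falling) correlate strongly with SPAD,
and they are configurable.

What passing the synthetic benchmark shows: the chain of segmentation →
channel means → indices → PCA → regressors recovers a planted monotone
SPAD–color relationship essentially exactly (validation R² ≈ 1, RMSE ≪ 1
SPAD unit at per-pixel noise SD 1). What it does **not** show: real
leaves vary in venation, curl, surface gloss, and pigment mixtures; real
lighting drifts; real SPAD–color relations are noisier and only locally
linear. Synthetic R²/RMSE values are therefore upper bounds on fidelity
of the *software*, not estimates of field accuracy, and are not
comparable to accuracies reported on real leaf datasets.

## Problem sizes and numerical details

Default test images are 256×256 (the generator supports arbitrary
sizes); the test suite uses 48–128 px images and datasets of 20–520
leaves, sizes chosen to exercise every code path at desk scale.
Degenerate inputs fail loudly: empty masks, all-background images,
constant targets, zero-variance feature columns, inverted bounds, even
median kernels, and unknown config keys each raise a typed error. Ratio
tolerances used in tests: 1e-12 for formula oracles, 1e-10 for the PCA/
SVD comparison, 1e-5 for the SVR/QP duality check (SLSQP oracle
precision), 0.05 for RVM slope recovery under noise.
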