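# Methods

This note documents the models, defaults and design decisions in `radgs`,
and what the synthetic experiments do and do not establish.

## Signal models and map fitting (`radgs.qmaps`)

ADC and T2 are mono-exponential decays fitted by **weighted log-linear
least squares** with weights S². The weighting de-biases the log transform
(log-domain noise has variance ∝ 1/S²), and the closed form makes the fit
deterministic and fast enough to vectorize over a whole slice. ADC is
fitted in mm²/s and reported in μm²/ms (exact ×10³); fits outside
[0, 10] μm²/ms or (0, 2000] ms are marked invalid. Pixels with any
non-positive sample on a log-fit path are marked invalid rather than
clamped — clamping would bias the log-domain regression.

The DCE curve is reduced to percent signal enhancement
`PSE(t) = 100·(S(t) − S_base)/S_base`, with `S_base` the mean of the first
`baseline_frames` samples (default 3; the reference signal of PSE is not
standardized, so it is configurable) and the time axis re-zeroed at the
last baseline frame. The empirical enhancement model
`PSE(t) = A(1 − e^{−αt})e^{−βt}` is fitted by bounded nonlinear least
squares with A ∈ [0, 1000] %, α ∈ [0, 10] /s, β ∈ [0, 1] /s, starting from
A₀ = max PSE, α₀ = ln2 / (time to half max), β₀ = 10⁻³/s; if that start
fails, a fixed 3×3×3 initializer grid is tried and the best-RMSE fit wins.
Bounds and initializers are this package's choices, made for robustness
and determinism.

α is reported as the fitted rate constant (1/s). Because some published
summaries quote α in %/s, the derived initial slope A·α (%/s) is also
exposed (`EMMFit.initial_slope`); the feature named `ALPHE` uses the
fitted α.

## ROI inflation (`radgs.roi`)

Inflation is iterated binary dilation with the 2×2 square structuring
element — the smallest square element, growing the mask by roughly one
pixel per turn. A 2×2 element has no center: the default origin is the
top-left cell, so each turn extends the mask one pixel toward increasing
row and column, matching the convention of common numeric platforms
(MATLAB's `strel('square', 2)` behaves this way). This drifts the mask
half a pixel per turn; `symmetric=True` alternates offsets between turns
to cancel the drift, and is off by default to match the platform
convention. Dilation clips at the image boundary; no anatomical constraint
is applied.

## Texture features (`radgs.texture`)

Map values under the (possibly inflated) ROI are uniformly quantized to 32
levels over the per-ROI min–max range. The level count and range are
configurable because co-occurrence feature scales depend on them; per-ROI
min–max is the default since the three maps share no absolute intensity
scale. Co-occurrence matrices are accumulated at unit distance for
0°/45°/90°/135°, admitting a pair only when **both** pixels are inside the
ROI and valid in the map (texture is ROI-restricted), counted
symmetrically, and normalized to probabilities. Entropy uses the natural
logarithm. The six features use the standard normalized forms; correlation
is defined as 0 when a marginal is degenerate. The 4-direction average is
the arithmetic mean of per-direction features, not a feature of the summed
matrix; directions with no admissible pair are excluded from the average.

Note that with normalized matrices, energy, homogeneity and IDM are ≤ 1 by
construction. Published tables that quote such features with magnitudes in
the tens or hundreds imply unnormalized co-occurrence counts; this package
standardizes on the normalized forms and treats those published values
only as class-summary parameters for the synthetic generator, never as
quantities to match.

## Feature selection and statistics (`radgs.selection`)

ReliefF runs a full deterministic pass (every sample, no subsampling),
with k = 10 nearest hits/misses (k is a convention; the KNN *classifier's*
k = 5 is a separate setting), Manhattan distance on range-normalized
features, prior-weighted miss contributions, and neighbor ties broken by
lowest sample index. Range normalization keeps weights in [−1, 1].
Retention keeps weights > 0, ordered descending.

The one-way ANOVA screen (p < 0.05) over the three Gleason groups is
computed and reported but does not gate the binary-task feature sets —
those use ReliefF alone. The binary contrasts use Welch's unequal-variance
two-tailed t-test.

## Balancing and classification (`radgs.balance`, `radgs.classify`)

SMOTE uses k = 5 Euclidean minority neighbors and one shared δ ~ U(0, 1)
per synthetic row (the classic formulation); every non-majority class is
raised to the majority count, and each synthetic row records its two
parent indices so the cross-validation driver can assert that no test-fold
row ever parents a training synthetic. Balancing, feature z-scoring and
the SVM hyperparameter search are all fitted on training rows only.

The SVM grid is C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³}, selected by an
inner stratified 3-fold search on the training fold (nested, so the
leakage guarantee stays intact) with deterministic first-best
tie-breaking; multiclass uses one-vs-one. KNN is k = 5 Euclidean with vote
ties resolved by the single nearest neighbor's label. Gaussian naive Bayes
uses empirical priors and a configurable misclassification-cost matrix
(0/1 by default, i.e. posterior argmax).

Folds are stratified (with a 13-vs-37 imbalance, unstratified 5-fold
splits frequently produce degenerate test folds) and lesion-level; the
cohort design does not address multiple lesions per patient, so no
patient-level grouping is applied by default.

## Synthetic data (`radgs.synthetic`)

**Feature tables** draw each feature independently from class-conditional
normals parameterized by the published class means/SDs; no feature
covariance is published, so independence is a deliberate simplification.
The published "a/b" column order is not stated; the first value is read as
the clinically-significant (resp. Gleason 3+4) group, with a `swap` flag.
Default counts are the reference cohort's: 37 significant vs 13
non-significant, and 29 vs 8 for the grade task.

**Phantoms** are 120×120 grids (1.5 mm in-plane DWI geometry) with smooth
background maps (ADC 1.8 μm²/ms, T2 150 ms, α 0.15/s, A 60 %), a random
star-convex lesion of radius ≈ min(shape)/8, and a drawn ROI produced by
eroding the true lesion by 2 pixels — encoding the premise that drawn ROIs
under-cover the lesion. Per Gleason group the lesion mean parameters
shift (ADC 1.30/1.18/1.08 μm²/ms, T2 105/96/89 ms, α 0.27/0.30/0.33 /s, A
85/92/98 % for 3+3 / 3+4 / ≥4+3) with 10 % per-lesion lognormal-like
jitter, and textured deviations are added as smoothed Gaussian random
fields. The interior texture is nearly class-independent (amplitude
5 %·(1 + 0.2·het), grain 2.2 − 0.6·het pixels, het = 0.35/0.65/1.0);
the rim between drawn ROI and true lesion carries the class texture
scaled by `margin_heterogeneity` (default 2): amplitude
5 %·margin·(0.3 + 1.5·het) with class-specific grain 2.5/1.8/1.2 px.
This concentrates grade information in the infiltrative margin, so ROI
inflation — and only inflation — can recover it; that is the mechanism
under test, and the generator's defaults are calibrated to produce a
moderate, not saturated, level-0 accuracy (~0.75–0.85) so the inflation
effect has headroom. Signals are synthesized exactly from the truth maps
through the three signal models and corrupted with additive Gaussian
noise (defaults 10/5/1 signal units ≈ 1 % of each modality's baseline;
Gaussian rather than Rician for analytic tractability). Per-case seeds
derive from the master seed by a fixed counter scheme; every output is a
pure function of (config, seed).

No quantitative description of per-class lesion texture exists to match,
so the texture model's only contract is ordinal: higher-grade phantoms
have higher drawn-ROI co-occurrence entropy on average, and
margin-heterogeneity cohorts show a non-negative inflation accuracy gain.

## Experiment orchestration (`radgs.experiment`)

The inflation sweep re-extracts features and re-runs ReliefF selection at
every level (a `freeze_selection` flag reuses the level-0 set instead);
selection runs once per level on the full level table, outside the CV
loop, matching the original analysis style. If no feature attains a
positive weight the sweep falls back to the full feature set with a
warning rather than aborting. If accuracy is still rising at the last
planned level the sweep extends one extra level. Sweeps over phantom
cohorts use the ground-truth parameter maps by default: map-fitting
fidelity is established separately (noiseless inversion to ≤10⁻⁶/10⁻³
relative; ADC MAE ≈ 2 % at 1 % noise), and skipping ~14k per-pixel
nonlinear DCE fits per phantom keeps a 20-seed sweep to minutes. Passing
a `fitted_maps` closure analyzes refitted maps instead; the per-pixel
enhancement fit is then restricted to the lesion neighborhood.

## What passing tests show — and what they don't

The oracle tests (Minkowski dilation, brute-force GLCM, grid-search and
closed-form fit oracles, hand-unrolled ReliefF) establish that the
operations compute what they claim. The end-to-end tests establish that
the pipeline discriminates classes whose feature distributions match the
published summaries, scores at chance on noise, leaks nothing across
folds, and reproduces the qualitative inflation effect on phantoms built
to contain it. They do **not** establish clinical performance: the
phantoms lack anatomy, Rician noise, registration error, inter-feature
covariance and scanner variability, and the published patient cohort is
not available for replication. Headline patient-level accuracies are
therefore never asserted by this package.

## Numerical details and degenerate inputs

Constant DWI series fit ADC = 0 (valid); constant echo series have no
decay and are invalid for T2. Constant ROIs quantize to a single level,
giving energy 1 / entropy 0 and correlation 0 by the degenerate-marginal
convention. lo = hi quantization ranges are treated as constant ROIs, not
errors. An all-constant feature column receives ReliefF weight exactly 0.
ANOVA columns with zero within-group variance get p = 0 when group means
separate and p = 1 otherwise. A minority class of one sample is an error
for SMOTE; k is reduced with a warning when the minority has n ≤ k.
Dilation is capped at 10 turns (beyond any level the analysis uses).
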