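# Methods

This note documents the models and procedures implemented in `quintex`, the
parameter choices that matter, and what the synthetic test bed does and does
not demonstrate.

## Quinary encoding and the riu4 alphabet

For a centre pixel with intensity `I_c`, each of `P` neighbours sampled on a
circle of radius `R` (bilinear interpolation off-grid; sampling starts at
the upper-left diagonal and proceeds clockwise) is quantised by

```
d(x) =  2  if x ≥ τ2        1  if τ1 ≤ x < τ2      0  if −τ1 ≤ x < τ1
       −1  if −τ2 ≤ x < −τ1    −2  if x < −τ2,       x = I_p − I_c
```

with adaptive thresholds `τ1 = p1·I_c`, `τ2 = p2·I_c` (defaults 2% and 7% of
the centre intensity). Intensities are cast to float before differencing to
avoid unsigned underflow. When `I_c = 0` the bands collapse (`τ1 = τ2 = 0`);
we then assign level 0 to a zero difference and `±2` by sign, keeping the
quantiser total. The quinary string splits into four binary sub-patterns
(levels 2, 1, −1, −2).

Each sub-pattern is coded rotation-invariantly. With `T` the circular
transition count:

* `T ∈ {0, 2}`: code = popcount (the classic uniform codes `0..P`);
* `T = 4`: the pattern has exactly two circular 1-runs with lengths
  `X ≤ Y` satisfying `X + Y ≤ P − 2`; code = `P + index(X, Y)` where
  `index(X, Y) = (X−1)(P−1−X) + Y − X + 1` enumerates the pairs from 1.
  The closed form equals the cumulative sum
  `Σ_{n=1}^{X−1}(P−3−2(n−1)) + (Y−X+1)` and is verified by enumeration to be
  a bijection onto `{1, …, ⌊(P−2)²/4⌋}` for every P used;
* otherwise: one unified code, `dim − 1`.

Per channel `dim = (P+2) + ⌊(P−2)²/4⌋`. A note on bit order: the basic
(non-invariant) code reads the written bit string as a standard binary
number, most-significant bit first — this is the convention that makes the
string `'00001111'` code to 15 — while rotation-invariant codes are
independent of the convention.

Codes are produced through per-P lookup tables over all `2^P` packed
patterns (the longest 1-run is found by iterated circular erosion), which
makes whole-image encoding a single table lookup per pixel and makes
exhaustive invariance checks cheap. A pixel is encoded only when all `P`
samples and their bilinear support pixels lie inside the breast mask, so
background intensities never leak into tissue codes; support pixels with
zero interpolation weight (exact grid hits) are not required.

## Intensity estimation and the K-function

Each (scale, sub-pattern, code) channel defines a point pattern: the valid
pixels carrying that code, observed in the breast window `W`. Its intensity
is estimated by a leave-one-out Gaussian kernel smoother,
`λ̂(x_i) = Σ_{j≠i} G_σ(x_i − x_j) / e(x_i)`, where `e(x)` is the kernel mass
inside `W` (edge-corrected density estimation). The bandwidth defaults to
`σ = 0.15·√|W|` pixels — a fixed fraction of the window's linear size, so
that the estimate captures the large-scale density trend rather than the
point-to-point fluctuations the K-function is meant to measure. Integer-grid
patterns use a separable-convolution fast path; the exact pairwise path is
used otherwise, and the two agree to well under 1%. Estimates are floored at
`10⁻¹⁰/|W|` so reciprocals stay finite.

The border-corrected inhomogeneous K estimator is

```
K(r) = |W| · Σ_{i: b_i>r} Σ_{j≠i} 1{‖x_i−x_j‖ ≤ r} / (λ̂_i λ̂_j)
       / ( Σ_i 1/λ̂_i · Σ_{j: b_j>r} 1/λ̂_j )
```

where `b_i` is the distance from `x_i` to the boundary of `W`, computed from
a Euclidean distance transform of the window padded with a zero ring (the
image frame counts as boundary) minus half a pixel (the geometric boundary
runs along pixel faces). Only points whose full disc of radius `r` lies
inside `W` act as reference points, which removes edge bias; radii with no
eligible reference point yield an undefined (NaN) `K(r)` that is excluded
from averages. On seeded Poisson patterns with known intensity the
Monte-Carlo mean of this estimator tracks `πr²` to within about 1% over
`r = 1..10` in a 100×100 window with ~500 points. The estimator is not
mathematically guaranteed to be monotone in `r` (the reference set shrinks
as `r` grows), although it is in practice on dense patterns.

Pairwise distances are exact (k-d tree within `r_max`); no distance binning
is applied.

The K-spectrum assigns each channel
`d̄ = mean_{r=1..s} [K(r) − πr²]` over integer radii `r = 1..10` by default
(valid radii up to 25 are supported; the short range concentrates on the
microstructure scale). Channels with fewer than two points, or mean over
only the defined radii otherwise, keep the vector length fixed at the
channel count; empty or all-undefined channels contribute 0. The bandwidth
σ and the edge-mass field are computed once per image and shared across
channels; λ̂ itself is re-estimated per channel, since each channel is its
own point process.

## Features, selection, classification

Histograms are per-plane L1-normalised by default (size invariance); raw
counts remain available because the dominant-pattern-set criterion is
defined on counts. DPS accumulates training histograms bin-wise, sorts
descending, and keeps the minimal prefix covering `n%` of the mass
(`n = 95` by default; the threshold is configurable since no single value is
canonical). For concatenated vectors DPS accumulates `|value|`, as
K-deviations may be negative. RFE eliminates by smallest squared linear-SVM
coefficient (C = 1), one feature per step below 200 remaining features and
5% per step above (runtime); FIR uses seeded random-forest impurity
importances. All ties break by (score desc, name asc) so rankings are
bit-reproducible.

The classifier is an explicit one-against-all SVM (one binary machine per
class, argmax of decision margins). Grid search covers kernels RBF, Poly,
Sigmoid with decade-spaced `γ ∈ [10⁻⁴, 10³]`, `C ∈ [10⁻³, 10⁴]` and degrees
1–6 (Poly only), selected by inner stratified-CV accuracy with ties toward
the simpler model (RBF over Poly over Sigmoid, then smaller C, then smaller
γ). Standardisation is fitted on training folds only. CV schemes: repeated
stratified k-fold (woman-grouped when IDs are present, so no woman spans
train and test — asserted at run time), leave-one-woman-out, and
leave-one-image-out. CA is averaged over folds; AUCROC is macro one-vs-rest
on decision margins (pooled when folds are singletons); κ, macro F1, MCC and
the confusion matrix are computed on pooled out-of-fold predictions. The
paired CV t-test uses the per-fold accuracy differences with `df = k − 1`;
a Nadeau–Bengio-corrected variant (variance factor `1/k + n_test/n_train`)
is available behind a flag because fold overlap makes the plain test
optimistic.

In the orchestrated pipeline, feature ranking is fitted once on the full
dataset before the outer CV (the selection-then-evaluate protocol common in
this literature). This is optimistic relative to nesting the selection in
every fold; conclusions drawn from the pipeline's absolute accuracies should
account for that, and the test bed only relies on the much weaker
above-chance claim.

## Preprocessing

Segmentation: percentile contrast stretch (1st–99th), Otsu threshold,
morphological closing then opening with a 5 px disc, largest connected
component. The contrast stretch is a deliberate, simple stand-in for more
elaborate enhancement schemes; the downstream descriptor thresholds are
relative to the centre intensity, so the choice mostly affects mask quality,
not codes. Pectoral removal (MLO views): 2-cluster k-means on intensities in
the designated top-corner quadrant, the bright corner-touching component is
taken as muscle, its tissue-side boundary is smoothed with a degree-2
polynomial per row and the corner side removed; if no well-separated bright
cluster exists the mask is returned unchanged with a warning. Denoising is a
3×3 median filter applied before bicubic rescaling (scale factors
1, 1/2, 1/4, 1/8, 1/16); masks are resampled nearest-neighbour and
re-binarised. The optional square ROI is anchored at the mask centroid,
starts at the bounding-box-inscribed square and shrinks until ≥95% of its
pixels are inside the mask (minimum 32 px). The 95% rule is this package's
own concrete choice; with a concave (crescent) mask it can stop at a square
slightly larger than the largest fully inscribed one.

## Synthetic test bed

Phantoms are half-ellipse "breast" windows on a dark background with a
smooth intensity ramp, Gaussian noise (σ = 4 grey levels on a ~90-level
tissue base), and class-dependent microstructure: density class `k ∈ 1..4`
plants `6k` Gaussian blobs and `3k` thin bright stripes. Default image size
is 128 px; the default dataset is 40 images (10 per class), two images per
synthetic woman so grouped CV is exercised. All generators are pure
functions of their seed. Point-pattern generators provide CSR (per-pixel
thinning), Matérn-style parent–offspring clusters, and sequential-inhibition
hard-core patterns with known parameters, used as oracles for the
K-estimator's sign and calibration.

What passing tests show: the coding rules are exactly the published ones,
the descriptor is rotation invariant and complete over its alphabet, the K
machinery is calibrated on known regimes, and the pipeline separates
classes whose microstructure differs. What they do not show: performance on
real mammograms — the phantoms have none of the grey-level statistics,
vendor variation, annotation noise or anatomical structure of FFDM/SFM
data, and the published headline accuracies on INbreast/MIAS require those
datasets and their expert labels. The synthetic 4-class problem is much
easier than BI-RADS grading; the end-to-end check is therefore a
plumbing-and-signal test (significantly above 25% chance under grouped
folds), not an accuracy claim.

## Numerical and runtime choices

Code tables are cached per (P, variant); `P = 18` costs ~0.5 MB and
milliseconds. K-spectra dominate runtime (~1–2 s per 128 px image over 656
channels); the end-to-end evaluation in the test suite uses an
RBF-only reduced grid and a fixed 128-feature RFE cut, and completes in
about 1.5 minutes. Exhaustive invariance checks run for `P ≤ 14`;
`P = 18` is sampled (10⁵ strings) because `2^18` rotations × 18 shifts are
still cheap but scalar cross-checks are not. Monte-Carlo tolerances (5% on
mean CSR K over 200 replicates) follow from the observed ~1% bias and the
replicate standard error, with headroom for seed variation.
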