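# Methods

This note documents the models, conventions and design choices behind
`spikecam`, in the order data flows through the toolkit.

## Grad-CAM on detection layers

For a tapped detection layer with post-activation feature maps `A^k_ij`
(`K` channels, `H x W` positions) and a scalar class score `y`, the channel
weight is the spatial mean of the gradient,
`alpha_k = (1/Z) sum_ij dy/dA^k_ij` with `Z = H*W`, and the map is
`L = ReLU(sum_k alpha_k A^k)`.  Two conventions matter:

* **One CAM per (image, layer).**  A single backward pass of `y` produces
  one map per layer; all labeled objects in the image are scored against
  that one map.  Per-instance attribution (one backward pass per box) is
  deliberately out of scope.
* **Raw values are kept.**  Attention-region extraction depends only on
  strict positivity of `L`, so no normalization is applied outside
  rendering.  Min–max normalization (all-zero maps stay zero; constant
  positive maps normalize to 1) exists only inside the heatmap renderer,
  where the overlay alpha is `opacity * normalized value` — unattended
  pixels always show the unmodified base image.

### Upsampling

Layer-resolution maps are lifted to image resolution before thresholding.
The default is separable bilinear interpolation with *pixel-center
alignment* (output pixel `x` samples source coordinate
`(x + 0.5) * src/dst - 0.5`, clamped at the edges); nearest-neighbour is
available and preserves the multiset of distinct values.  The interpolation
is implemented directly rather than through a library resampler because
resamplers differ in alignment and filtering conventions, and the
convention here is part of the method's definition (it determines which
pixels count as attended).  Downsampling is rejected: detection layers are
never finer than the image.

## Attention scoring

The attention area is `{(i,j) : L_upsampled(i,j) > t}` with threshold
`t = 0` by default (strict positivity); `t` is exposed because a user may
want to ignore numerically tiny activations.  The score of a box is

    S = |attention ∩ box| / |box|.

Taking the intersection with the box (rather than the raw ratio of the two
areas) keeps `S` in [0, 1] even when attention spreads far beyond objects —
the characteristic failure of large-receptive-field layers — and makes
`S = 1` mean "the object is fully attended".  Attention is not partitioned
among overlapping boxes; a pixel may count toward several objects, since no
principled assignment rule exists without per-instance attribution.

Coordinates are 0-based, half-open, y down.  GWHD-style packed box strings
are inclusive-corner and gain one pixel on the max corners when read; YOLO
labels convert with floor on the min corner and ceil on the max corner
(with a 1e-9 nudge against binary-decimal drift), clipped to the image.

## Per-layer statistics

Scores are tabulated in ten 0.1-wide bins, half-open except the last
(`[0.9, 1.0]` closed), each with the object proportion and the mean object
pixel size.  Bin membership uses `floor(10*S + 1e-9)`: scores are ratios of
small integers, and the nudge keeps exact decimals such as 3/10 in their
mathematically correct bin; it is far below the resolution of any realistic
box area (spacing ≥ 1e-6 for boxes under a megapixel).  Proportions are
exact rationals on counts (`Fraction(100*count, total)`), so they sum to
100 % identically; display rounding (0.1 % / 1 px / 3 decimals on mean
score) happens only in text reports.  Zero-score objects appear both inside
the first bin and in the separate zero-score audit — the two views
intentionally overlap, as they answer different questions (distribution
shape vs. outright failure).

Layers are ranked by ascending zero-score proportion with descending mean
score as tie-break and canonical small → medium → large order as the final
tie-break.  Mean score alone cannot rank layers: a layer can post the
highest mean score while ignoring a third of all objects, and the
zero-score share is what separates loose attention from outright failure.

## Refinement advisor

Verdicts are a function of the zero-score proportion alone: *poor* at
≥ 25 %, *excellent* at ≤ 20 % (boundaries inclusive; when the two
thresholds coincide the poor rule wins).  The defaults were chosen so that
zero-score proportions around 17.5 % / 4 % / 30 % for the small / medium /
large layers — the regime in which removing the large head, adding a
micro-scale companion and enhancing the medium head is the documented
remedy — classify with comfortable margin; both cutoffs are configurable
and echoed in every report.  Actions are a fixed map from (layer role,
verdict); the rationale string carries all per-layer statistics, not only
the deciding one, because a human reviewing the advice wants the full
picture.  The advisor emits recommendations only and never edits a network:
architecture surgery is framework-specific.

## Toy detector

The bundled detector exists so the pipeline has a real gradient source
without a deep-learning framework.  It is a stack of strided 3x3
convolutions with ReLU, zero-padded so each output is `ceil(in/stride)` —
this keeps cumulative strides composing exactly, so the default five-layer
stack taps detection layers at strides 8/16/32 and successive tapped layers
differ by exactly a factor of 4 in pixel count, mirroring the scale
structure of single-stage detectors.  Each tapped layer feeds a fixed
single-channel 1x1-convolution response head; `y` is the sum of the
selected heads over all positions (all three by default, selectable), and
the head definition is recorded in a `definition_tag` since real detectors
expose many inequivalent notions of a class score.  Weights are seeded
uniform in [-0.5, 0.5] with zero biases: reproducible, and sign-diverse so
the ReLU in the CAM actually clips.  Backpropagation is written by hand
(transposed-convolution scatter plus ReLU masks); the tapped quantity is
the post-ReLU output, so the gradient `dy/dA` excludes the layer's own ReLU
mask — matching the finite-difference oracle, which perturbs stored
activations and re-runs only the downstream pass.  Backprop agrees with
central differences (eps = 1e-4) to relative error well below 1e-4.

For real detectors, the bridge is two `.npy` files per (image, layer) —
values and gradients, `K x H x W` float32 — with no numerical
transformation on load.  What `y` should be for a multi-box detector
(per-detection, summed, confidence-filtered) is left to the producer of the
dump and recorded in the tag.

## Synthetic scenes

Scenes emulate labeled field plots: elliptical blobs with Gaussian radial
profile `exp(-ln(10) * r²)` on a mottled green background, so a blob's
support — pixels above 10 % of its peak — is exactly the sampled ellipse
interior, and the ground-truth box is the tight box of that pixel support.
Blob areas are log-normal; the four presets use median areas 833 / 1230 /
2472 / 15271 px² to span the small-to-large regimes seen across multi-site
wheat imagery.  Dispersion defaults to sigma = 0.35 (log-scale), a
realistic within-site spread that keeps the mean within ~6 % of the median.
Aspect ratios are uniform in [0.35, 0.8] with uniform orientation
(spikes are elongated); placement rejects candidates whose box IoU with any
accepted box exceeds 0.2, retrying up to 200 times per object before
raising.  Everything derives from one seed.

What the generator does **not** model: photorealistic texture, occlusion by
leaves/awns, lighting gradients, growth stages, or label noise.  Tests
passing on these scenes therefore demonstrate the correctness of the
pipeline's computations and the internal consistency of its statistics —
not that any particular real detector's layers will score well.

`corrupt_detections` degrades ground truth into detector-like output:
boxes jittered by N(0, sd) corner offsets with confidence
`exp(-mean|offset| / (4*sd))` (so confidence decreases in jitter magnitude
and unjittered boxes score 1.0), independent drops, and binomial false
positives at plausible sizes with confidence in [0.05, 0.5].

## Detection metrics

Matching is greedy in descending confidence (ties by original index); each
detection claims the unmatched same-image ground truth of highest IoU at or
above the threshold (ties to the earlier ground-truth index), default
threshold 0.5.  One ground truth matches at most one detection, so
TP + FN = number of ground truths at every confidence cut.  AP integrates
the interpolated-precision envelope over all distinct recall steps
(all-point interpolation); the 11-point variant is available for comparison
with older toolchains.  With ground truth present but zero detections the
curve is empty and AP is reported as 0.

## Problem sizes

The test suite and the acceptance script run the brute-force oracles on
small instances — layers up to 8x8x8 for the CAM oracle, 8x8 inputs for
finite differences, ≤ 5 detections vs ≤ 4 ground truths for exhaustive
matching — and the end-to-end batch uses three 128x128 scenes with 8
objects each; these sizes already exercise every code path (multi-channel,
multi-layer, ties, empty attention) while keeping the whole suite at a few
seconds.

## Known limitations

* The toy detector is untrained; which layers "win" on synthetic scenes is
  a property of the seeded random weights, not evidence about trained
  networks.  The pipeline's value on real detectors enters through the dump
  bridge.
* `S` weights all attended pixels equally; a soft score using CAM magnitude
  is out of scope.
* The advisor's verdicts consider the zero-score proportion only; mean
  score and visual confusion are reported in the rationale but do not
  change the action.
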