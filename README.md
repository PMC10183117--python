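# spikecam

Interpretive analysis of multi-scale object-detection layers with Grad-CAM,
built for wheat spike phenotyping.

Single-stage detectors (the YOLO family and friends) predict objects from
several detection layers at increasing stride — a *small*-object head at
stride 8, a *medium* head at 16, a *large* head at 32.  When object sizes in
the imagery are skewed, some of those heads contribute little or even hurt.
`spikecam` quantifies each layer's contribution directly: it computes a
gradient-weighted class-activation map per layer, scores every labeled
object by how much of it the layer attends to, aggregates those scores into
per-layer statistics, and turns the statistics into concrete architecture
advice (drop a head, add a finer-scale head, enhance a head's features).
The toolkit is aimed at crop-phenotyping practitioners who train spike/head
detectors on field imagery, and comes with a fully self-contained toy
multi-scale detector and a synthetic scene generator so the whole pipeline
runs and is tested without any deep-learning framework or dataset download.

## The method

For one detection layer with feature maps `A^k` (channel `k`, spatial grid
`H x W`) and a scalar class score `y`, the channel weights and the
class-activation map are

    alpha_k = (1/Z) * sum_ij  dy/dA^k_ij ,       Z = H * W
    L       = ReLU( sum_k alpha_k * A^k )

The *attention area* of the layer is the set of image pixels where the
(bilinearly upsampled) map `L` is strictly positive.  Each ground-truth box
gets an attention score per layer,

    S = |attention area ∩ box| / |box| ∈ [0, 1],

the fraction of the object the layer attends to.  Scores are tabulated in
0.1-wide bins with the proportion of objects and mean object size per bin,
and each layer gets a *zero-score audit*: the share of objects it ignores
entirely (S = 0) and their mean size.  A rule-based advisor classifies each
layer from its zero-score proportion (poor ≥ 25 %, excellent ≤ 20 %, both
configurable) and maps verdicts to actions: remove a poor large-scale
layer, keep an excellent small-scale layer and add a micro-scale companion,
enhance the features of an excellent medium-scale layer.

Detection quality is evaluated with greedy IoU matching (threshold 0.5),
`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`, and AP as the area under
the interpolated precision–recall curve.

## Worked example

Generate three seeded 128x128 synthetic spike scenes (8 objects each,
median object area 400 px²), run the Grad-CAM pass of the bundled toy
detector, aggregate, and ask for advice:

```sh
spikecam synth   --out-dir data --n-scenes 3 --seed 17 \
                 --image-size 128,128 --n-objects 8 --median-area 400
spikecam explain --images-dir data --labels data/labels.csv \
                 --out-dir explain --weight-seed 1
spikecam stats   --records explain/records.csv --out-dir stats
spikecam advise  --stats stats/stats.json --out-dir advice
```

The `stats` step prints the layer ranking:

```
layer ranking (ascending zero-score proportion, mean score tie-break):
  1. small: zero-score 0.0%, mean score 0.511, range [0.049, 0.864]  <- best
  2. large: zero-score 41.7%, mean score 0.423, range [0.000, 1.000]
  3. medium: zero-score 83.3%, mean score 0.047, range [0.000, 0.425]  <- worst
```

and `advise` turns it into actions:

```
refinement advice (poor >= 25.0% zero-score, excellent <= 20.0%):
  small: excellent -> keep + add_micro_scale_companion
      zero-score proportion 0.0%, mean score 0.511, score range [0.049, 0.864], n=24 -> excellent
  medium: poor -> keep
      zero-score proportion 83.3%, mean score 0.047, score range [0.000, 0.425], n=24 -> poor
  large: poor -> remove
      zero-score proportion 41.7%, mean score 0.423, score range [0.000, 1.000], n=24 -> poor
```

Read it as: on these scenes this (untrained, seeded) toy network's
small-scale head attends to every labeled object (zero-score share 0 %,
average coverage 51 % of each box), so it is worth keeping and
complementing with an even finer head; the large-scale head misses 41.7 %
of objects outright and should be removed.  The machine-readable versions
(`stats/stats.json`, `advice/advice.json`, per-layer CAM dumps and masks)
land next to the text reports.

Real detectors plug in the same way: dump each tapped layer's feature maps
and gradients as one `K x H x W` float32 `.npy` file each
(`<image>__<layer>__values.npy` / `...__grads.npy`) and load them with
`spikecam.load_external_activations`; everything downstream is identical.
`spikecam eval` scores a detection CSV against ground truth
(`AP 1.0000 (recall 1.0000, ...)` for perfect self-detections), and
`spikecam render` blends a dumped CAM over its image as a heatmap PNG.

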