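"""Toy multi-scale convolutional detector with hand-written forward/backward.

The interpretive-analysis pipeline needs, for every detection layer, the
feature maps ``A^k_ij`` and the gradients ``dy/dA^k_ij`` of a scalar network
output ``y`` (the prediction score for the object class).  Production
detectors provide these through an ML framework; this module provides them
from a small, fully self-contained convolutional network so the whole
pipeline is testable end-to-end without any deep-learning dependency.

The default network mirrors the scale structure of single-stage detectors:
three tapped detection layers at cumulative strides 8, 16 and 32, so that
successive detection-layer pixel counts differ by a factor of 4.  Each tapped
layer feeds a fixed single-channel 1x1-convolution response head; ``y`` is
the sum of the selected heads over all spatial positions.  Gradients are
computed by hand-written backpropagation through the strided convolutions
and ReLUs, and can be cross-checked against central finite differences.

External detectors are bridged by dumping per-layer feature maps and
gradients as ``.npy`` arrays (one ``K x H x W`` float32 array per file) and
loading them with :func:`load_external_activations`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InputError, LayerLookupError

__all__ = [
    "LayerActivation",
    "TargetScore",
    "ToyDetectorSpec",
    "ToyDetector",
    "build_toy_detector",
    "forward_backward",
    "finite_difference_gradients",
    "load_external_activations",
    "DEFAULT_LAYER_ORDER",
]

#: Canonical ordering of detection-layer identifiers, shallow to deep.
DEFAULT_LAYER_ORDER = ("small", "medium", "large")


@dataclass
class LayerActivation:
    """One detection layer's feature maps ``A^k_ij`` and gradients ``dy/dA^k_ij``.

    ``values`` and ``gradients`` are ``K x H x W`` arrays; ``stride`` is the
    cumulative downsampling factor of this layer relative to the input image.
    The Grad-CAM normalizer ``Z`` is always ``H * W`` and is exposed as a
    property rather than stored.
    """

    layer_id: str
    values: np.ndarray
    gradients: np.ndarray
    stride: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.values.ndim != 3 or self.gradients.ndim != 3:
            raise InputError(
                f"layer {self.layer_id!r}: values/gradients must be K x H x W, "
                f"got {self.values.shape} and {self.gradients.shape}"
            )
        if self.values.shape != self.gradients.shape:
            raise InputError(
                f"layer {self.layer_id!r}: values shape {self.values.shape} != "
                f"gradients shape {self.gradients.shape}"
            )

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]

    @property
    def Z(self) -> int:
        """Spatial normalizer: number of positions per feature map."""
        return self.height * self.width


@dataclass(frozen=True)
class TargetScore:
    """The scalar network output ``y`` whose gradients drive the attribution.

    ``definition_tag`` records how ``y`` was formed (which response heads were
    summed), since different detectors expose different notions of a class
    prediction score.
    """

    value: float
    definition_tag: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InputError(f"target score must be finite, got {self.value!r}")


@dataclass(frozen=True)
class ToyDetectorSpec:
    """Configuration of the toy detector.

    Parameters
    ----------
    input_size
        ``(height, width)`` of input images in pixels.
    layer_specs
        Ordered ``(kernel_size, stride, in_channels, out_channels)`` tuples,
        one per convolution.  Zero padding keeps each output at
        ``ceil(input / stride)`` so cumulative strides compose exactly.
    detection_layers
        Maps layer identifiers (``"small"``/``"medium"``/``"large"``) to
        0-based indices into ``layer_specs``; cumulative strides of the
        tapped layers must be strictly increasing in that order.
    weight_seed
        Seed for the deterministic uniform[-0.5, 0.5] weight initialization.
    y_layers
        Which tapped layers' response heads contribute to ``y`` (default all).
    """

    input_size: tuple[int, int] = (64, 64)
    layer_specs: tuple[tuple[int, int, int, int], ...] = (
        (3, 2, 3, 8),
        (3, 2, 8, 12),
        (3, 2, 12, 16),
        (3, 2, 16, 16),
        (3, 2, 16, 16),
    )
    detection_layers: tuple[tuple[str, int], ...] = (
        ("small", 2),
        ("medium", 3),
        ("large", 4),
    )
    weight_seed: int = 0
    y_layers: tuple[str, ...] = DEFAULT_LAYER_ORDER

    def __post_init__(self) -> None:
        if len(self.input_size) != 2 or any(s <= 0 for s in self.input_size):
            raise ConfigurationError(f"invalid input_size {self.input_size!r}")
        if not self.layer_specs:
            raise ConfigurationError("layer_specs must not be empty")
        for idx, (k, s, cin, cout) in enumerate(self.layer_specs):
            if k <= 0 or s <= 0:
                raise ConfigurationError(
                    f"layer {idx}: kernel and stride must be positive, got k={k}, s={s}"
                )
            if cin <= 0 or cout <= 0:
                raise ConfigurationError(
                    f"layer {idx}: channel counts must be positive, got {cin}->{cout}"
                )
        for idx in range(1, len(self.layer_specs)):
            if self.layer_specs[idx][2] != self.layer_specs[idx - 1][3]:
                raise ConfigurationError(
                    f"layer {idx}: in_channels {self.layer_specs[idx][2]} != "
                    f"previous out_channels {self.layer_specs[idx - 1][3]}"
                )
        taps = dict(self.detection_layers)
        if len(taps) != len(self.detection_layers):
            raise ConfigurationError("duplicate detection-layer identifiers")
        strides = self.cumulative_strides()
        tapped = []
        for name, li in self.detection_layers:
            if not 0 <= li < len(self.layer_specs):
                raise ConfigurationError(f"detection layer {name!r} taps missing layer {li}")
            tapped.append(strides[li])
        if any(b <= a for a, b in zip(tapped, tapped[1:])):
            raise ConfigurationError(
                "cumulative strides of tapped layers must be strictly increasing "
                f"(small < medium < large), got {tapped}"
            )
        unknown = set(self.y_layers) - set(taps)
        if unknown:
            raise ConfigurationError(f"y_layers reference unknown taps: {sorted(unknown)}")

    def cumulative_strides(self) -> list[int]:
        """Cumulative downsampling factor after each convolution."""
        out, acc = [], 1
        for _, s, _, _ in self.layer_specs:
            acc *= s
            out.append(acc)
        return out

    @property
    def tap_indices(self) -> dict[str, int]:
        return dict(self.detection_layers)


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output size and (top/left, total) zero padding for ceil-mode convolution."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Strided 2-D convolution (cross-correlation), zero padded to ceil(in/stride)."""
    cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    ho, pt, ph = _same_pad(h, k, stride)
    wo, pl, pw = _same_pad(wd, k, stride)
    xp = np.zeros((cin, h + ph, wd + pw), dtype=x.dtype)
    xp[:, pt : pt + h, pl : pl + wd] = x
    out = np.zeros((cout, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            patch = xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride]
            out += np.einsum("oc,chw->ohw", w[:, :, i, j], patch)
    return out


def _conv2d_input_grad(
    g: np.ndarray, w: np.ndarray, stride: int, in_shape: tuple[int, int, int]
) -> np.ndarray:
    """Gradient of the convolution output w.r.t. its input (transposed conv)."""
    cin, h, wd = in_shape
    cout, _, k, _ = w.shape
    ho, pt, ph = _same_pad(h, k, stride)
    wo, pl, pw = _same_pad(wd, k, stride)
    gp = np.zeros((cin, h + ph, wd + pw), dtype=g.dtype)
    for i in range(k):
        for j in range(k):
            gp[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += np.einsum(
                "oc,ohw->chw", w[:, :, i, j], g
            )
    return gp[:, pt : pt + h, pl : pl + wd]


@dataclass
class ToyDetector:
    """A built toy detector: seeded conv weights plus per-tap response heads.

    ``head_weights[name]`` is the 1x1-convolution weight vector (one entry per
    channel of the tapped layer) of the single-channel response head whose
    global spatial sum contributes to ``y``.  Biases are zero everywhere.
    """

    spec: ToyDetectorSpec
    conv_weights: list[np.ndarray] = field(repr=False)
    head_weights: dict[str, np.ndarray] = field(repr=False)

    def forward(self, image: np.ndarray) -> list[np.ndarray]:
        """Run all convolutions; returns the post-ReLU output of every layer."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 3 or image.shape[2] != self.spec.layer_specs[0][2]:
            raise InputError(
                f"expected H x W x {self.spec.layer_specs[0][2]} image, got {image.shape}"
            )
        if image.shape[:2] != tuple(self.spec.input_size):
            raise InputError(
                f"image size {image.shape[:2]} does not match spec {self.spec.input_size}"
            )
        if not np.all(np.isfinite(image)):
            raise InputError("image contains non-finite pixel values")
        x = image.transpose(2, 0, 1)
        acts = []
        for w, (_, s, _, _) in zip(self.conv_weights, self.spec.layer_specs):
            x = np.maximum(_conv2d(x, w, s), 0.0)
            acts.append(x)
        return acts

    def head_sum(self, name: str, activation: np.ndarray) -> float:
        """Response of one head: sum over positions of its 1x1 conv output."""
        return float(np.einsum("k,khw->", self.head_weights[name], activation))

    def target_from_activations(self, acts: Sequence[np.ndarray]) -> float:
        taps = self.spec.tap_indices
        return sum(self.head_sum(name, acts[taps[name]]) for name in self.spec.y_layers)


def build_toy_detector(spec: ToyDetectorSpec) -> ToyDetector:
    """Build a detector with weights reproducible from ``spec.weight_seed``."""
    rng = np.random.default_rng(spec.weight_seed)
    conv_weights = [
        rng.uniform(-0.5, 0.5, size=(cout, cin, k, k))
        for (k, _, cin, cout) in spec.layer_specs
    ]
    # head draw order is fixed by the spec's detection-layer declaration order
    head_weights = {
        name: rng.uniform(-0.5, 0.5, size=spec.layer_specs[li][3])
        for name, li in spec.detection_layers
    }
    return ToyDetector(spec=spec, conv_weights=conv_weights, head_weights=head_weights)


def forward_backward(
    detector: ToyDetector, image: np.ndarray
) -> tuple[list[LayerActivation], TargetScore]:
    """Forward pass plus hand-written backpropagation of ``y``.

    Returns one :class:`LayerActivation` per tapped detection layer, in the
    declared (small -> medium -> large) order, holding the post-ReLU feature
    maps and the gradients of ``y`` with respect to them, and the
    :class:`TargetScore` ``y`` itself.
    """
    spec = detector.spec
    acts = detector.forward(image)
    y = detector.target_from_activations(acts)

    # grads[l] accumulates dy/d(output of layer l)
    grads = [np.zeros_like(a) for a in acts]
    taps = spec.tap_indices
    for name in spec.y_layers:
        li = taps[name]
        # d(head sum)/dA^k_ij is the head weight of channel k at every position
        grads[li] += detector.head_weights[name][:, None, None]
    for li in range(len(acts) - 1, 0, -1):
        # the tapped value is the post-ReLU output, so the layer's own ReLU
        # mask applies only when propagating further down
        masked = grads[li] * (acts[li] > 0)
        grads[li - 1] += _conv2d_input_grad(
            masked, detector.conv_weights[li], spec.layer_specs[li][1], acts[li - 1].shape
        )

    strides = spec.cumulative_strides()
    layer_acts = [
        LayerActivation(
            layer_id=name,
            values=acts[li].copy(),
            gradients=grads[li].copy(),
            stride=strides[li],
        )
        for name, li in spec.detection_layers
    ]
    tag = "head_sum:" + "+".join(spec.y_layers)
    return layer_acts, TargetScore(value=y, definition_tag=tag)


def finite_difference_gradients(
    detector: ToyDetector, image: np.ndarray, layer_id: str, epsilon: float = 1e-4
) -> np.ndarray:
    """Central-difference estimate of ``dy/dA^k_ij`` at one tapped layer.

    Each stored activation entry of the tapped layer is perturbed by
    ``+/- epsilon`` and the downstream forward pass re-run; the head
    contributions of shallower taps are unaffected and cancel in the
    difference.  Intended as an independent oracle for ``forward_backward``.
    """
    if epsilon <= 0:
        raise ConfigurationError(f"epsilon must be positive, got {epsilon}")
    spec = detector.spec
    taps = spec.tap_indices
    if layer_id not in taps:
        raise LayerLookupError(f"unknown detection layer {layer_id!r}")
    li = taps[layer_id]
    acts = detector.forward(image)

    def downstream_y(a_mod: np.ndarray) -> float:
        local = list(acts)
        local[li] = a_mod
        x = a_mod
        for lj in range(li + 1, len(spec.layer_specs)):
            x = np.maximum(_conv2d(x, detector.conv_weights[lj], spec.layer_specs[lj][1]), 0.0)
            local[lj] = x
        return detector.target_from_activations(local)

    base = acts[li]
    grad = np.zeros_like(base)
    it = np.nditer(base, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        plus = base.copy()
        plus[idx] += epsilon
        minus = base.copy()
        minus[idx] -= epsilon
        grad[idx] = (downstream_y(plus) - downstream_y(minus)) / (2.0 * epsilon)
    return grad


def load_external_activations(
    values_path, gradients_path, layer_id: str, stride: int
) -> LayerActivation:
    """Load a detection layer dumped by an external framework.

    Both files must hold a single ``K x H x W`` array in NumPy ``.npy``
    format (any real dtype; float32 little-endian is the documented dump
    convention).  No numerical transformation is applied.
    """
    values = np.load(values_path)
    gradients = np.load(gradients_path)
    if values.ndim != 3 or gradients.ndim != 3:
        raise FormatError(
            f"expected K x H x W arrays, got shapes {values.shape} and {gradients.shape}"
        )
    if values.shape != gradients.shape:
        raise FormatError(
            f"values shape {values.shape} does not match gradients shape {gradients.shape}"
        )
    return LayerActivation(
        layer_id=layer_id,
        values=values.astype(float),
        gradients=gradients.astype(float),
        stride=stride,
    )
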