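"""Grad-CAM: channel weights, class-activation maps, upsampling, rendering.

For a detection layer with feature maps ``A^k`` and gradients of the class
score ``y``, the channel weight is the spatial mean of the gradient,

    alpha_k = (1/Z) * sum_ij dy/dA^k_ij,        Z = H * W,

and the class-activation map is the ReLU-rectified weighted sum

    L = ReLU( sum_k alpha_k * A^k ).

The map lives at layer resolution; :func:`upsample_cam` lifts it to image
resolution (bilinear by default) so it can be compared against labeled
boxes.  Raw (unnormalized) values are kept throughout — attention-region
extraction depends only on strict positivity — and min-max normalization
happens solely inside :func:`render_heatmap`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .detector import LayerActivation
from .errors import InputError

__all__ = ["ChannelWeights", "CamMap", "channel_weights", "gradcam_map", "upsample_cam", "render_heatmap"]


@dataclass(frozen=True)
class ChannelWeights:
    """Per-channel Grad-CAM weights ``alpha_k`` for one detection layer."""

    layer_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.ndim != 1:
            raise InputError(f"weights must be a 1-D vector, got shape {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise InputError("channel weights contain non-finite values")


@dataclass(frozen=True)
class CamMap:
    """A non-negative class-activation map at layer or image resolution."""

    layer_id: str
    resolution_tag: str  # "layer" or "image"
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise InputError(f"CAM must be 2-D, got shape {self.values.shape}")
        if self.resolution_tag not in ("layer", "image"):
            raise InputError(f"unknown resolution_tag {self.resolution_tag!r}")
        if self.values.size and self.values.min() < 0:
            raise InputError("CAM values must be non-negative (post-ReLU)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def channel_weights(activation: LayerActivation) -> ChannelWeights:
    """alpha_k = mean over spatial positions of dy/dA^k_ij, per channel."""
    if activation.Z == 0:
        raise InputError(f"layer {activation.layer_id!r} has an empty spatial grid")
    if not np.all(np.isfinite(activation.gradients)):
        raise InputError(f"layer {activation.layer_id!r} has non-finite gradients")
    alpha = activation.gradients.sum(axis=(1, 2)) / activation.Z
    return ChannelWeights(layer_id=activation.layer_id, weights=alpha)


def gradcam_map(activation: LayerActivation, weights: ChannelWeights) -> CamMap:
    """ReLU( sum_k alpha_k A^k ) at layer resolution."""
    if len(weights.weights) != activation.channels:
        raise InputError(
            f"weight count {len(weights.weights)} does not match "
            f"channel count {activation.channels}"
        )
    raw = np.einsum("k,khw->hw", weights.weights, activation.values)
    return CamMap(layer_id=activation.layer_id, resolution_tag="layer", values=np.maximum(raw, 0.0))


def _axis_coords(n_out: int, n_src: int) -> np.ndarray:
    """Pixel-center aligned source coordinates for each output pixel."""
    return (np.arange(n_out) + 0.5) * (n_src / n_out) - 0.5


def upsample_cam(cam: CamMap, image_size: tuple[int, int], method: str = "bilinear") -> CamMap:
    """Lift a layer-resolution CAM to image resolution.

    ``method="bilinear"`` interpolates between pixel centers with edge
    clamping; ``"nearest"`` replicates source pixels (preserving the multiset
    of distinct values).  Downsampling is not supported.
    """
    if cam.resolution_tag != "layer":
        raise InputError("upsample_cam expects a layer-resolution CAM")
    if method not in ("bilinear", "nearest"):
        raise InputError(f"unknown upsampling method {method!r}")
    ho, wo = image_size
    hs, ws = cam.shape
    if ho < hs or wo < ws:
        raise InputError(
            f"target size {image_size} smaller than source {cam.shape}; downsampling unsupported"
        )
    v = cam.values
    if method == "nearest":
        yi = np.minimum(((np.arange(ho) + 0.5) * hs / ho).astype(int), hs - 1)
        xi = np.minimum(((np.arange(wo) + 0.5) * ws / wo).astype(int), ws - 1)
        out = v[np.ix_(yi, xi)]
    else:
        ys = np.clip(_axis_coords(ho, hs), 0, hs - 1)
        xs = np.clip(_axis_coords(wo, ws), 0, ws - 1)
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        y1 = np.minimum(y0 + 1, hs - 1)
        x1 = np.minimum(x0 + 1, ws - 1)
        ty = (ys - y0)[:, None]
        tx = (xs - x0)[None, :]
        rows0 = v[y0][:, x0]
        rows1 = v[y0][:, x1]
        rows2 = v[y1][:, x0]
        rows3 = v[y1][:, x1]
        out = (
            rows0 * (1 - ty) * (1 - tx)
            + rows1 * (1 - ty) * tx
            + rows2 * ty * (1 - tx)
            + rows3 * ty * tx
        )
    return CamMap(layer_id=cam.layer_id, resolution_tag="image", values=out)


def render_heatmap(
    cam: CamMap, image: np.ndarray, opacity: float = 0.5, cmap: str = "jet"
) -> np.ndarray:
    """Overlay a CAM heatmap on an RGB image; returns a uint8 H x W x 3 image.

    The CAM is min-max normalized to [0, 1] (all-zero maps stay zero; a
    constant positive map normalizes to 1), mapped through the named
    matplotlib color ramp, and alpha-blended with per-pixel alpha equal to
    ``opacity * normalized_value`` — so unattended pixels always show the
    pure base image.
    """
    if cam.resolution_tag != "image":
        raise InputError("render_heatmap expects an image-resolution CAM")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.shape[:2] != cam.shape:
        raise InputError(f"image size {image.shape[:2]} does not match CAM size {cam.shape}")
    if not 0.0 <= opacity <= 1.0:
        raise InputError(f"opacity must lie in [0, 1], got {opacity}")

    v = cam.values
    vmax, vmin = float(v.max(initial=0.0)), float(v.min(initial=0.0))
    if vmax <= 0.0:
        norm = np.zeros_like(v)
    elif vmax == vmin:  # constant positive map
        norm = np.ones_like(v)
    else:
        norm = (v - vmin) / (vmax - vmin)

    base = image.astype(float) / 255.0 if image.dtype == np.uint8 else image.astype(float)
    ramp = colormaps[cmap](norm)[..., :3]
    alpha = (opacity * norm)[..., None]
    blended = (1.0 - alpha) * base + alpha * ramp
    return (np.clip(blended, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
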