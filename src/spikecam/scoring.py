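"""Attention regions and per-object attention scores.

The attention area of a detection layer is the set of image pixels where the
(upsampled) Grad-CAM map is strictly positive — the "non-empty" region.  The
attention score of one labeled object on one layer is

    S = |attention area  inside the box| / |box|,

i.e. the fraction of the ground-truth box covered by the layer's attention.
The intersection with the box keeps S in [0, 1] even when attention spills
far beyond the object, which is exactly the failure mode large-receptive-
field layers exhibit.  A pixel may count toward several overlapping boxes;
attention is not partitioned.

Coordinates are 0-based, half-open (``x_min <= x < x_max``), y increasing
downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import DEFAULT_LAYER_ORDER
from .errors import ConfigurationError, InputError, LayerLookupError
from .gradcam import CamMap

__all__ = [
    "GroundTruthBox",
    "AttentionMask",
    "AttentionScoreRecord",
    "attention_mask",
    "attention_score",
    "score_all",
    "layer_sort_key",
]


@dataclass(frozen=True)
class GroundTruthBox:
    """A labeled object box in half-open pixel coordinates."""

    image_id: str
    box_id: str
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise InputError(
                f"degenerate box {self.box_id!r} on {self.image_id!r}: "
                f"({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise InputError(f"box {self.box_id!r} has negative coordinates")

    @property
    def area(self) -> int:
        """Pixel area (the object's spike size)."""
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class AttentionMask:
    """Binary attention region of one detection layer at image resolution."""

    layer_id: str
    image_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=bool))
        if self.grid.ndim != 2:
            raise InputError(f"mask grid must be 2-D, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class AttentionScoreRecord:
    """Attention score S of one box on one detection layer."""

    image_id: str
    box_id: str
    layer_id: str
    score: float
    spike_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise InputError(f"score must lie in [0, 1], got {self.score}")
        if self.spike_size < 1:
            raise InputError(f"spike_size must be >= 1, got {self.spike_size}")


def attention_mask(cam: CamMap, threshold: float = 0.0, image_id: str = "") -> AttentionMask:
    """Binarize an image-resolution CAM: attended iff value > threshold.

    The default threshold 0 keeps every strictly positive pixel, matching
    the "non-empty Grad-CAM value" definition of the attention area.
    """
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    if cam.resolution_tag != "image":
        raise InputError("attention_mask expects an image-resolution CAM")
    return AttentionMask(layer_id=cam.layer_id, image_id=image_id, grid=cam.values > threshold)


def attention_score(mask: AttentionMask, box: GroundTruthBox) -> AttentionScoreRecord:
    """S = attended pixels inside the box / box area."""
    h, w = mask.shape
    if box.x_max > w or box.y_max > h:
        raise InputError(
            f"box {box.box_id!r} ({box.x_min},{box.y_min})-({box.x_max},{box.y_max}) "
            f"exceeds mask bounds {h}x{w}"
        )
    inside = int(mask.grid[box.y_min : box.y_max, box.x_min : box.x_max].sum())
    return AttentionScoreRecord(
        image_id=box.image_id,
        box_id=box.box_id,
        layer_id=mask.layer_id,
        score=inside / box.area,
        spike_size=box.area,
    )


def layer_sort_key(layer_id: str):
    """Canonical ordering: small -> medium -> large, then others alphabetically."""
    try:
        return (0, DEFAULT_LAYER_ORDER.index(layer_id))
    except ValueError:
        return (1, layer_id)


def score_all(masks, boxes) -> list[AttentionScoreRecord]:
    """Score every (box, layer) pair.

    ``masks`` is an iterable of :class:`AttentionMask` (or a mapping
    ``(image_id, layer_id) -> AttentionMask``).  The layers of each image are
    the union of layer ids seen across all masks; a box whose image is
    missing a layer's mask raises a lookup error naming the offending pair.
    Records are ordered by (image_id, box_id, canonical layer order).
    """
    if hasattr(masks, "values") and not isinstance(masks, (list, tuple)):
        mask_list = list(masks.values())
    else:
        mask_list = list(masks)
    index: dict[tuple[str, str], AttentionMask] = {}
    for m in mask_list:
        index[(m.image_id, m.layer_id)] = m
    layers = sorted({m.layer_id for m in mask_list}, key=layer_sort_key)

    records = []
    for box in sorted(boxes, key=lambda b: (b.image_id, b.box_id)):
        for layer_id in layers:
            mask = index.get((box.image_id, layer_id))
            if mask is None:
                raise LayerLookupError(
                    f"no attention mask for image {box.image_id!r}, layer {layer_id!r}"
                )
            records.append(attention_score(mask, box))
    return records
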