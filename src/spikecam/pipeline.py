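"""High-level composition of the toolkit stages.

These helpers chain detector -> Grad-CAM -> attention masks -> score
records -> statistics -> advice so that the CLI, the test suite and batch
scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .advisor import AdvisorThresholds, RefinementAdvice, advise
from .detector import LayerActivation, TargetScore, ToyDetector, forward_backward
from .gradcam import CamMap, channel_weights, gradcam_map, upsample_cam
from .layerstats import LayerScoreStats, layer_summary
from .scoring import (
    AttentionMask,
    AttentionScoreRecord,
    GroundTruthBox,
    attention_mask,
    score_all,
)

__all__ = ["ExplainResult", "explain_image", "explain_batch", "summarize_records", "advise_from_records"]


@dataclass
class ExplainResult:
    """Everything the interpretive pass produces for one image."""

    image_id: str
    activations: list[LayerActivation]
    target: TargetScore
    cams: dict[str, CamMap]  # image-resolution, keyed by layer_id
    masks: dict[str, AttentionMask]
    records: list[AttentionScoreRecord]


def explain_image(
    detector: ToyDetector,
    image: np.ndarray,
    boxes: Sequence[GroundTruthBox],
    image_id: str = "scene",
    threshold: float = 0.0,
    upsample_method: str = "bilinear",
) -> ExplainResult:
    """One backward pass, per-layer CAMs/masks, and a score per (box, layer)."""
    activations, target = forward_backward(detector, image)
    image_size = image.shape[:2]
    cams: dict[str, CamMap] = {}
    masks: dict[str, AttentionMask] = {}
    for act in activations:
        cam = upsample_cam(gradcam_map(act, channel_weights(act)), image_size, upsample_method)
        cams[act.layer_id] = cam
        masks[act.layer_id] = attention_mask(cam, threshold=threshold, image_id=image_id)
    records = score_all(list(masks.values()), boxes) if boxes else []
    return ExplainResult(
        image_id=image_id,
        activations=activations,
        target=target,
        cams=cams,
        masks=masks,
        records=records,
    )


def explain_batch(
    detector: ToyDetector,
    scenes: Sequence[tuple[str, np.ndarray, Sequence[GroundTruthBox]]],
    threshold: float = 0.0,
    upsample_method: str = "bilinear",
) -> list[ExplainResult]:
    return [
        explain_image(detector, image, boxes, image_id, threshold, upsample_method)
        for image_id, image, boxes in scenes
    ]


def summarize_records(records: Sequence[AttentionScoreRecord]) -> list[LayerScoreStats]:
    """Per-layer summaries from a mixed record list, canonical layer order."""
    from .scoring import layer_sort_key

    by_layer: dict[str, list[AttentionScoreRecord]] = {}
    for r in records:
        by_layer.setdefault(r.layer_id, []).append(r)
    return [
        layer_summary(by_layer[layer], layer_id=layer)
        for layer in sorted(by_layer, key=layer_sort_key)
    ]


def advise_from_records(
    records: Sequence[AttentionScoreRecord],
    thresholds: AdvisorThresholds = AdvisorThresholds(),
) -> RefinementAdvice:
    return advise(summarize_records(records), thresholds)
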