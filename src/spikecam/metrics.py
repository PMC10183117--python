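"""Detection evaluation: IoU matching, precision/recall, average precision.

Detections are matched to ground-truth boxes greedily in descending
confidence order: each detection claims the still-unmatched ground truth of
highest IoU at or above the threshold (default 0.5) and becomes a true
positive, otherwise a false positive; unmatched ground truths are false
negatives.  Sweeping the confidence cut over the sorted detections yields
the precision-recall curve

    precision = TP / (TP + FP),        recall = TP / (TP + FN),

and AP is the area under that curve using the interpolated-precision
envelope (precision at recall r replaced by the maximum precision attained
at any recall >= r), summed over all distinct recall steps.  Classic
11-point interpolation is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, StatisticsError
from .scoring import GroundTruthBox

__all__ = [
    "Detection",
    "MatchOutcome",
    "PRCurve",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate_detections",
]


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence in [0, 1] (half-open pixel coords)."""

    image_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise InputError(
                f"degenerate detection on {self.image_id!r}: "
                f"({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence must lie in [0, 1], got {self.confidence}")


def iou(a, b) -> float:
    """Intersection over union of two boxes (objects with x_min..y_max)."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    area_a = (a.x_max - a.x_min) * (a.y_max - a.y_min)
    area_b = (b.x_max - b.x_min) * (b.y_max - b.y_min)
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchOutcome:
    """TP/FP flag per detection (confidence-ordered) plus the FN count basis."""

    flags: list[tuple[float, bool]]  # (confidence, is_true_positive), conf desc
    n_ground_truth: int

    @property
    def tp(self) -> int:
        return sum(1 for _, t in self.flags if t)

    @property
    def fp(self) -> int:
        return sum(1 for _, t in self.flags if not t)

    @property
    def fn(self) -> int:
        return self.n_ground_truth - self.tp


def match_detections(
    detections, ground_truths, iou_threshold: float = 0.5
) -> MatchOutcome:
    """Greedy confidence-descending matching within each image.

    Ties in confidence are broken by the detection's original list index;
    ties in IoU by the earlier ground-truth index.  One ground truth matches
    at most one detection.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ConfigurationError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    dets = list(detections)
    gts = list(ground_truths)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched = [False] * len(gts)
    flags: list[tuple[float, bool]] = []
    for di in order:
        d = dets[di]
        best_iou, best_gi = 0.0, None
        for gi, g in enumerate(gts):
            if matched[gi] or g.image_id != d.image_id:
                continue
            v = iou(d, g)
            if v >= iou_threshold and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None:
            matched[best_gi] = True
            flags.append((d.confidence, True))
        else:
            flags.append((d.confidence, False))
    return MatchOutcome(flags=flags, n_ground_truth=len(gts))


@dataclass
class PRCurve:
    """Confidence-swept (recall, precision) points and the resulting AP."""

    recalls: np.ndarray
    precisions: np.ndarray
    confidences: np.ndarray
    ap: float | None = None

    @property
    def final_recall(self) -> float:
        """Recall with every detection accepted (0 when there are none)."""
        return float(self.recalls[-1]) if len(self.recalls) else 0.0


def precision_recall(outcome: MatchOutcome) -> PRCurve:
    """Cumulative precision/recall as the confidence threshold sweeps down."""
    if not outcome.flags and outcome.n_ground_truth == 0:
        raise StatisticsError("no detections and no ground truths to evaluate")
    tp = np.cumsum([1 if t else 0 for _, t in outcome.flags])
    fp = np.cumsum([0 if t else 1 for _, t in outcome.flags])
    conf = np.array([c for c, _ in outcome.flags], dtype=float)
    n = len(outcome.flags)
    precisions = tp / np.maximum(tp + fp, 1) if n else np.empty(0)
    if outcome.n_ground_truth:
        recalls = tp / outcome.n_ground_truth if n else np.empty(0)
    else:
        recalls = np.zeros(n)
    return PRCurve(recalls=np.asarray(recalls, dtype=float),
                   precisions=np.asarray(precisions, dtype=float),
                   confidences=conf)


def average_precision(curve: PRCurve, method: str = "interp_all") -> float:
    """Area under the PR curve.

    ``interp_all`` (default) integrates the interpolated-precision envelope
    over every distinct recall step; ``interp_11`` averages the envelope at
    the 11 recall points 0.0, 0.1, ..., 1.0.
    """
    if method not in ("interp_all", "interp_11"):
        raise ConfigurationError(f"unknown AP method {method!r}")
    if len(curve.recalls) == 0:
        raise StatisticsError("cannot integrate an empty precision-recall curve")
    # envelope: running max of precision from the high-recall end
    mrec = np.concatenate([[0.0], curve.recalls])
    mpre = np.concatenate([[0.0], curve.precisions])
    env = np.maximum.accumulate(mpre[::-1])[::-1]
    if method == "interp_11":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = mrec >= r - 1e-12
            pts.append(float(env[mask].max()) if mask.any() else 0.0)
        return float(np.mean(pts))
    steps = np.flatnonzero(np.diff(mrec) > 0)
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * env[steps + 1]))


def evaluate_detections(
    detections, ground_truths, iou_threshold: float = 0.5, method: str = "interp_all"
) -> PRCurve:
    """Match, sweep and integrate in one call; returns the curve with its AP.

    With ground truths present but zero detections the curve is empty and
    AP is 0 (nothing was found).
    """
    outcome = match_detections(detections, ground_truths, iou_threshold)
    curve = precision_recall(outcome)
    curve.ap = average_precision(curve, method) if len(curve.recalls) else 0.0
    return curve
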