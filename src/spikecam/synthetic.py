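"""Synthetic labeled spike scenes and corrupted detections.

Generates RGB field-plot-like images containing elliptical
Gaussian-intensity blobs standing in for wheat spikes, together with tight
ground-truth bounding boxes, so every stage of the toolkit is testable
without external imagery.  Blob areas follow a log-normal distribution whose
median is configurable; four presets mirror the spread of mean spike sizes
observed across multi-site wheat phenotyping imagery (roughly 800 to
15,000 px² per object):

====================  ==================
preset                median area (px²)
====================  ==================
``ethz-like``         833
``arvalis-like``      1230
``usask-like``        2472
``inrae-like``        15271
====================  ==================

A blob's *support* is the pixel set where its intensity exceeds 10% of its
peak, which for the Gaussian profile used here is exactly the interior of
the sampled ellipse; the ground-truth box is the tight bounding box of that
support.  Placement rejects candidates whose box IoU with any accepted box
exceeds ``max_overlap_iou`` (with a retry cap), and everything is driven by
a single seed.

:func:`corrupt_detections` degrades ground truth into detector-like output
(jittered boxes with confidence decreasing in jitter magnitude, random
drops, appended false positives) so that evaluation metrics can be exercised
against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GenerationError
from .metrics import Detection
from .scoring import GroundTruthBox

__all__ = [
    "SceneSpec",
    "PRESET_MEDIAN_AREAS",
    "preset_scene_spec",
    "generate_scene",
    "corrupt_detections",
]

#: Median blob areas (px²) of the four site-like presets.
PRESET_MEDIAN_AREAS = {
    "ethz-like": 833.0,
    "arvalis-like": 1230.0,
    "usask-like": 2472.0,
    "inrae-like": 15271.0,
}

# Gaussian profile exp(-ln(10) * r^2) crosses 10% of peak exactly at r = 1,
# i.e. on the sampled ellipse boundary.
_LN10 = math.log(10.0)

_RETRY_CAP = 200


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic labeled scene.

    ``median_area`` and ``dispersion`` are the log-normal area parameters
    (median in px², dispersion = standard deviation of log area).
    ``aspect_ratio_range`` bounds the minor/major axis ratio of each blob.
    """

    image_size: tuple[int, int] = (256, 256)
    n_objects: int = 12
    median_area: float = 2472.0
    dispersion: float = 0.35
    aspect_ratio_range: tuple[float, float] = (0.35, 0.8)
    max_overlap_iou: float = 0.2
    background: str = "textured"
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.image_size):
            raise ConfigurationError(f"invalid image_size {self.image_size!r}")
        if self.n_objects < 0:
            raise ConfigurationError("n_objects must be >= 0")
        if self.median_area <= 0 or self.dispersion < 0:
            raise ConfigurationError("median_area must be > 0 and dispersion >= 0")
        lo, hi = self.aspect_ratio_range
        if not 0 < lo <= hi <= 1:
            raise ConfigurationError(f"invalid aspect_ratio_range {self.aspect_ratio_range!r}")
        if not 0.0 <= self.max_overlap_iou < 1.0:
            raise ConfigurationError("max_overlap_iou must lie in [0, 1)")
        if self.background not in ("flat", "textured"):
            raise ConfigurationError(f"unknown background {self.background!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def preset_scene_spec(name: str, seed: int = 0, **overrides) -> SceneSpec:
    """A SceneSpec for one of the four site-like presets.

    The large-object preset (``inrae-like``) uses a bigger canvas and fewer
    objects so that placement stays feasible.
    """
    if name not in PRESET_MEDIAN_AREAS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_MEDIAN_AREAS)}"
        )
    base = dict(median_area=PRESET_MEDIAN_AREAS[name], seed=seed)
    if name == "inrae-like":
        base.update(image_size=(512, 512), n_objects=6)
    base.update(overrides)
    return SceneSpec(**base)


def sample_areas(spec: SceneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n blob areas from the spec's log-normal size distribution."""
    return np.exp(rng.normal(math.log(spec.median_area), spec.dispersion, size=n))


def _box_iou(a: tuple, b: tuple) -> float:
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union if union else 0.0


def _support_box(
    cx: float, cy: float, a: float, b: float, theta: float, size: tuple[int, int]
):
    """Pixel support (r² <= 1) of a rotated ellipse and its tight box.

    Returns (box, local intensity patch, patch origin) or None when no pixel
    center falls inside the ellipse.
    """
    h, w = size
    ex = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ey = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    x0 = max(int(math.floor(cx - ex)), 0)
    x1 = min(int(math.ceil(cx + ex)) + 1, w)
    y0 = max(int(math.floor(cy - ey)), 0)
    y1 = min(int(math.ceil(cy + ey)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    xs = np.arange(x0, x1) + 0.5 - cx
    ys = np.arange(y0, y1) + 0.5 - cy
    dx, dy = np.meshgrid(xs, ys)
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
    r2 = u * u + v * v
    support = r2 <= 1.0
    if not support.any():
        return None
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    box = (x0 + cols[0], y0 + rows[0], x0 + cols[-1] + 1, y0 + rows[-1] + 1)
    intensity = np.where(support, np.exp(-_LN10 * r2), 0.0)
    return box, intensity, (y0, x0)


# muted field-plot palette: greenish canopy background, straw-colored blobs
_BG_COLOR = np.array([0.16, 0.24, 0.10])
_BLOB_COLOR = np.array([0.85, 0.75, 0.35])


def generate_scene(
    spec: SceneSpec, image_id: str = "scene"
) -> tuple[np.ndarray, list[GroundTruthBox]]:
    """Render one seeded scene; returns (H x W x 3 float image in [0,1], boxes)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    image = np.tile(_BG_COLOR, (h, w, 1))
    if spec.background == "textured":
        # low-frequency mottle: coarse noise bilinearly blown up to full size
        coarse = rng.normal(0.0, 1.0, size=(max(h // 16, 2), max(w // 16, 2)))
        yy = np.linspace(0, coarse.shape[0] - 1, h)
        xx = np.linspace(0, coarse.shape[1] - 1, w)
        y0 = np.floor(yy).astype(int)
        x0 = np.floor(xx).astype(int)
        y1 = np.minimum(y0 + 1, coarse.shape[0] - 1)
        x1 = np.minimum(x0 + 1, coarse.shape[1] - 1)
        ty = (yy - y0)[:, None]
        tx = (xx - x0)[None, :]
        mottle = (
            coarse[y0][:, x0] * (1 - ty) * (1 - tx)
            + coarse[y0][:, x1] * (1 - ty) * tx
            + coarse[y1][:, x0] * ty * (1 - tx)
            + coarse[y1][:, x1] * ty * tx
        )
        image = image + 0.06 * mottle[..., None]

    boxes: list[GroundTruthBox] = []
    accepted: list[tuple] = []
    areas = sample_areas(spec, spec.n_objects, rng)
    for i in range(spec.n_objects):
        placed = False
        for _ in range(_RETRY_CAP):
            area = float(areas[i])
            aspect = rng.uniform(*spec.aspect_ratio_range)
            a = math.sqrt(area / (math.pi * aspect))  # semi-major
            b = aspect * a  # semi-minor
            theta = rng.uniform(0.0, math.pi)
            ex = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
            ey = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
            if 2 * ex >= w or 2 * ey >= h:
                areas[i] = float(sample_areas(spec, 1, rng)[0])  # too big for canvas
                continue
            cx = rng.uniform(ex, w - ex)
            cy = rng.uniform(ey, h - ey)
            hit = _support_box(cx, cy, a, b, theta, spec.image_size)
            if hit is None:
                continue
            box, intensity, (py, px) = hit
            if any(_box_iou(box, prev) > spec.max_overlap_iou for prev in accepted):
                continue
            peak = rng.uniform(0.6, 0.95)
            patch = image[py : py + intensity.shape[0], px : px + intensity.shape[1]]
            blend = (peak * intensity)[..., None]
            patch[:] = (1 - blend) * patch + blend * _BLOB_COLOR
            accepted.append(box)
            boxes.append(
                GroundTruthBox(
                    image_id=image_id,
                    box_id=f"box{i:03d}",
                    x_min=int(box[0]),
                    y_min=int(box[1]),
                    x_max=int(box[2]),
                    y_max=int(box[3]),
                )
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place object {i} within {_RETRY_CAP} attempts "
                f"(scene too crowded for max_overlap_iou={spec.max_overlap_iou})"
            )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), boxes


def corrupt_detections(
    boxes,
    jitter_sd: float = 2.0,
    drop_rate: float = 0.0,
    false_positive_rate: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] | None = None,
) -> list[Detection]:
    """Turn ground truth into detector-like output with known degradation.

    Each kept box is jittered by independent N(0, jitter_sd) corner offsets;
    its confidence decays exponentially in the mean absolute offset, so
    unjittered boxes score 1.0.  ``drop_rate`` removes boxes independently;
    ``false_positive_rate`` appends, per ground-truth box, a Bernoulli
    random spurious box (uniform location/size, low confidence) — this
    requires ``image_size``.
    """
    if jitter_sd < 0:
        raise ConfigurationError("jitter_sd must be >= 0")
    for name, rate in (("drop_rate", drop_rate), ("false_positive_rate", false_positive_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {rate}")
    if false_positive_rate > 0 and image_size is None:
        raise ConfigurationError("image_size is required when false_positive_rate > 0")

    rng = np.random.default_rng(seed)
    boxes = list(boxes)
    detections: list[Detection] = []
    for box in boxes:
        if rng.uniform() < drop_rate:
            continue
        off = rng.normal(0.0, jitter_sd, size=4) if jitter_sd > 0 else np.zeros(4)
        x0, y0 = box.x_min + off[0], box.y_min + off[1]
        x1, y1 = box.x_max + off[2], box.y_max + off[3]
        if x1 <= x0 + 1:
            x0, x1 = box.x_min, box.x_max
        if y1 <= y0 + 1:
            y0, y1 = box.y_min, box.y_max
        mag = float(np.mean(np.abs(off)))
        conf = float(np.exp(-mag / (4.0 * jitter_sd))) if jitter_sd > 0 else 1.0
        detections.append(
            Detection(
                image_id=box.image_id,
                x_min=float(x0),
                y_min=float(y0),
                x_max=float(x1),
                y_max=float(y1),
                confidence=conf,
            )
        )
    if false_positive_rate > 0 and boxes:
        h, w = image_size
        sizes = np.array([b.area for b in boxes], dtype=float)
        typical = math.sqrt(float(np.median(sizes)))
        image_ids = sorted({b.image_id for b in boxes})
        n_fp = int(rng.binomial(len(boxes), false_positive_rate))
        for _ in range(n_fp):
            side_x = max(rng.uniform(0.5, 1.5) * typical, 2.0)
            side_y = max(rng.uniform(0.5, 1.5) * typical, 2.0)
            cx = rng.uniform(side_x / 2, w - side_x / 2)
            cy = rng.uniform(side_y / 2, h - side_y / 2)
            detections.append(
                Detection(
                    image_id=image_ids[int(rng.integers(len(image_ids)))],
                    x_min=cx - side_x / 2,
                    y_min=cy - side_y / 2,
                    x_max=cx + side_x / 2,
                    y_max=cy + side_y / 2,
                    confidence=float(rng.uniform(0.05, 0.5)),
                )
            )
    return detections
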