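"""Readers and writers for every on-disk format the toolkit touches.

* images, masks, heatmaps — PNG via Pillow;
* boxes — GWHD-style CSV (one-box-per-row or packed boxes-string dialect)
  and YOLO txt labels;
* detections, score records, bin tables, PR points — CSV via pandas;
* statistics and advice — JSON;
* activations and CAMs — NumPy ``.npy`` (one float32 K x H x W or H x W
  array per file), the portable dump format any ML framework can write in
  one line.

Box CSVs use 0-based half-open pixel coordinates in the one-box-per-row
dialect.  Packed GWHD boxes-strings are inclusive-corner; reading converts
them to half-open by adding 1 to the max corners.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .advisor import RefinementAdvice
from .errors import ParseError, ValidationError
from .layerstats import LayerScoreStats
from .metrics import Detection, PRCurve
from .scoring import AttentionMask, AttentionScoreRecord, GroundTruthBox

__all__ = [
    "save_array",
    "load_array",
    "dump_name",
    "write_image_png",
    "read_image_png",
    "write_mask_png",
    "read_mask_png",
    "write_gwhd_csv",
    "read_gwhd_csv",
    "write_yolo_labels",
    "read_yolo_labels",
    "write_detections_csv",
    "read_detections_csv",
    "write_records_csv",
    "read_records_csv",
    "write_stats_csv",
    "write_stats_json",
    "read_stats_json",
    "write_pr_csv",
    "write_advice_json",
]


# ---------------------------------------------------------------- arrays

def save_array(array: np.ndarray, path) -> None:
    """Write one array as little-endian float32 ``.npy``."""
    np.save(path, np.asarray(array, dtype="<f4"), allow_pickle=False)


def load_array(path) -> np.ndarray:
    return np.load(path, allow_pickle=False)


def dump_name(image_id: str, layer_id: str, kind: str) -> str:
    """Canonical dump file name: <image_id>__<layer_id>__{values|grads|cam}.npy."""
    if kind not in ("values", "grads", "cam"):
        raise ValidationError(f"unknown dump kind {kind!r}")
    return f"{image_id}__{layer_id}__{kind}.npy"


# ---------------------------------------------------------------- images

def write_image_png(image: np.ndarray, path) -> None:
    """Save an RGB image; float arrays in [0,1] are scaled to uint8."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask_png(mask: AttentionMask, path) -> None:
    """1-bit attention mask as an 8-bit 0/255 PNG."""
    Image.fromarray((mask.grid.astype(np.uint8)) * 255).save(path)


def read_mask_png(path, layer_id: str = "", image_id: str = "") -> AttentionMask:
    grid = np.asarray(Image.open(path).convert("L")) > 127
    return AttentionMask(layer_id=layer_id, image_id=image_id, grid=grid)


# ---------------------------------------------------------------- boxes

_ROW_COLUMNS = ["image_id", "box_id", "x_min", "y_min", "x_max", "y_max"]


def write_gwhd_csv(boxes: Sequence[GroundTruthBox], path) -> None:
    """One-box-per-row dialect; round-trips exactly."""
    pd.DataFrame(
        [
            {
                "image_id": b.image_id,
                "box_id": b.box_id,
                "x_min": b.x_min,
                "y_min": b.y_min,
                "x_max": b.x_max,
                "y_max": b.y_max,
            }
            for b in boxes
        ],
        columns=_ROW_COLUMNS,
    ).to_csv(path, index=False)


def _box_from_row(row, line_no: int, image_size) -> GroundTruthBox:
    try:
        box = GroundTruthBox(
            image_id=str(row["image_id"]),
            box_id=str(row.get("box_id", f"box{line_no:03d}")),
            x_min=int(row["x_min"]),
            y_min=int(row["y_min"]),
            x_max=int(row["x_max"]),
            y_max=int(row["y_max"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"line {line_no}: malformed box row ({exc})") from exc
    except Exception as exc:  # degenerate box from scoring validation
        raise ValidationError(f"line {line_no}: {exc}") from exc
    if image_size is not None:
        h, w = image_size
        if box.x_max > w or box.y_max > h:
            raise ValidationError(f"line {line_no}: box exceeds image bounds {h}x{w}")
    return box


def read_gwhd_csv(path, image_size: Optional[tuple[int, int]] = None) -> list[GroundTruthBox]:
    """Read either GWHD dialect, validated and converted to half-open coords.

    Dialect is detected from the header: a ``boxes`` column selects the
    packed boxes-string form ("x y x y;..." with inclusive corners, +1
    applied to max corners on read); otherwise one-box-per-row columns
    ``image_id, x_min, y_min, x_max, y_max`` (optionally ``box_id``) are
    expected, already half-open.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc
    boxes: list[GroundTruthBox] = []
    if "boxes" in df.columns:
        id_col = "image_id" if "image_id" in df.columns else "image_name"
        if id_col not in df.columns:
            raise ParseError("packed dialect needs an image_id or image_name column")
        for ri, row in df.iterrows():
            line_no = ri + 2  # header is line 1
            packed = row["boxes"]
            if pd.isna(packed) or not str(packed).strip():
                continue
            for bi, quad in enumerate(str(packed).split(";")):
                quad = quad.strip()
                if not quad:
                    continue
                parts = quad.replace(",", " ").split()
                if len(parts) != 4:
                    raise ParseError(f"line {line_no}: bad box quadruple {quad!r}")
                try:
                    x0, y0, x1, y1 = (int(float(p)) for p in parts)
                except ValueError as exc:
                    raise ParseError(f"line {line_no}: non-numeric box {quad!r}") from exc
                # inclusive corners -> half-open
                synthetic_row = {
                    "image_id": row[id_col],
                    "box_id": f"box{bi:03d}",
                    "x_min": x0,
                    "y_min": y0,
                    "x_max": x1 + 1,
                    "y_max": y1 + 1,
                }
                boxes.append(_box_from_row(synthetic_row, line_no, image_size))
    else:
        missing = {"image_id", "x_min", "y_min", "x_max", "y_max"} - set(df.columns)
        if missing:
            raise ParseError(f"missing columns {sorted(missing)} in {path}")
        for ri, row in df.iterrows():
            boxes.append(_box_from_row(row, ri + 2, image_size))
    return boxes


def write_yolo_labels(boxes: Sequence[GroundTruthBox], path, image_size) -> None:
    """Write normalized "class cx cy w h" rows (single class 0)."""
    h, w = image_size
    lines = []
    for b in boxes:
        cx = (b.x_min + b.x_max) / 2.0 / w
        cy = (b.y_min + b.y_max) / 2.0 / h
        bw = (b.x_max - b.x_min) / w
        bh = (b.y_max - b.y_min) / h
        lines.append(f"0 {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, image_size, image_id: str = "") -> list[GroundTruthBox]:
    """YOLO txt rows to half-open pixel boxes.

    Rounding convention: floor of the min corner, ceil of the max corner,
    clipped to the image.
    """
    h, w = image_size
    image_id = image_id or Path(path).stem
    boxes = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(f"line {line_no}: expected 5 fields, got {len(parts)}")
        try:
            _, cx, cy, bw, bh = (float(p) for p in parts)
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-numeric field") from exc
        if not all(0.0 <= v <= 1.0 for v in (cx, cy, bw, bh)):
            raise ValidationError(f"line {line_no}: normalized coordinate outside [0, 1]")
        # 1e-9 nudge keeps exact decimal products (e.g. 0.55 * 100) from
        # drifting across the integer boundary in binary floating point
        x_min = max(int(np.floor((cx - bw / 2) * w + 1e-9)), 0)
        y_min = max(int(np.floor((cy - bh / 2) * h + 1e-9)), 0)
        x_max = min(int(np.ceil((cx + bw / 2) * w - 1e-9)), w)
        y_max = min(int(np.ceil((cy + bh / 2) * h - 1e-9)), h)
        boxes.append(
            GroundTruthBox(
                image_id=image_id,
                box_id=f"box{line_no - 1:03d}",
                x_min=x_min,
                y_min=y_min,
                x_max=x_max,
                y_max=y_max,
            )
        )
    return boxes


# ---------------------------------------------------------------- detections

def write_detections_csv(detections: Sequence[Detection], path) -> None:
    pd.DataFrame(
        [
            {
                "image_id": d.image_id,
                "x_min": d.x_min,
                "y_min": d.y_min,
                "x_max": d.x_max,
                "y_max": d.y_max,
                "confidence": d.confidence,
            }
            for d in detections
        ],
        columns=["image_id", "x_min", "y_min", "x_max", "y_max", "confidence"],
    ).to_csv(path, index=False)


def read_detections_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    missing = {"image_id", "x_min", "y_min", "x_max", "y_max", "confidence"} - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)} in {path}")
    dets = []
    for ri, row in df.iterrows():
        try:
            dets.append(
                Detection(
                    image_id=str(row["image_id"]),
                    x_min=float(row["x_min"]),
                    y_min=float(row["y_min"]),
                    x_max=float(row["x_max"]),
                    y_max=float(row["y_max"]),
                    confidence=float(row["confidence"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {ri + 2}: {exc}") from exc
    return dets


# ---------------------------------------------------------------- records

def write_records_csv(records: Sequence[AttentionScoreRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "box_id": r.box_id,
                "layer_id": r.layer_id,
                "score": r.score,
                "spike_size": r.spike_size,
            }
            for r in records
        ],
        columns=["image_id", "box_id", "layer_id", "score", "spike_size"],
    ).to_csv(path, index=False)


def read_records_csv(path) -> list[AttentionScoreRecord]:
    df = pd.read_csv(path)
    missing = {"image_id", "box_id", "layer_id", "score", "spike_size"} - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)} in {path}")
    return [
        AttentionScoreRecord(
            image_id=str(row["image_id"]),
            box_id=str(row["box_id"]),
            layer_id=str(row["layer_id"]),
            score=float(row["score"]),
            spike_size=int(row["spike_size"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------- statistics

def _stats_payload(stats: LayerScoreStats) -> dict:
    return {
        "layer_id": stats.layer_id,
        "n_records": stats.n_records,
        "score_min": stats.score_min,
        "score_max": stats.score_max,
        "mean_score": stats.mean_score,
        "zero_proportion_pct": stats.zero_proportion_pct,
        "zero_mean_spike_size": stats.zero_mean_spike_size,
        "zero_count": stats.zero_count,
        "bins": [
            {
                "lower": b.lower,
                "upper": b.upper,
                "count": b.count,
                "proportion_pct": b.proportion_pct,
                "mean_spike_size": b.mean_spike_size,
            }
            for b in stats.bins
        ],
    }


def write_stats_csv(stats_list: Sequence[LayerScoreStats], path) -> None:
    """One row per (layer, bin) at full precision."""
    rows = []
    for s in stats_list:
        for b in s.bins:
            rows.append(
                {
                    "layer_id": s.layer_id,
                    "lower": b.lower,
                    "upper": b.upper,
                    "count": b.count,
                    "proportion_pct": b.proportion_pct,
                    "mean_spike_size": b.mean_spike_size,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_stats_json(stats_list: Sequence[LayerScoreStats], path) -> None:
    payload = {s.layer_id: _stats_payload(s) for s in stats_list}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_stats_json(path) -> list[LayerScoreStats]:
    from .layerstats import ScoreBin
    from .scoring import layer_sort_key

    payload = json.loads(Path(path).read_text())
    stats = []
    for layer_id in sorted(payload, key=layer_sort_key):
        p = payload[layer_id]
        bins = [
            ScoreBin(
                lower=b["lower"],
                upper=b["upper"],
                count=b["count"],
                proportion_pct=b["proportion_pct"],
                mean_spike_size=b["mean_spike_size"],
            )
            for b in p["bins"]
        ]
        stats.append(
            LayerScoreStats(
                layer_id=p["layer_id"],
                n_records=p["n_records"],
                bins=bins,
                score_min=p["score_min"],
                score_max=p["score_max"],
                mean_score=p["mean_score"],
                zero_proportion_pct=p["zero_proportion_pct"],
                zero_mean_spike_size=p["zero_mean_spike_size"],
                zero_count=p.get("zero_count", 0),
                bin_counts=[b["count"] for b in p["bins"]],
            )
        )
    return stats


def write_pr_csv(curve: PRCurve, path) -> None:
    pd.DataFrame(
        {
            "confidence": curve.confidences,
            "recall": curve.recalls,
            "precision": curve.precisions,
        }
    ).to_csv(path, index=False)


def write_advice_json(advice: RefinementAdvice, path) -> None:
    Path(path).write_text(json.dumps(advice.to_dict(), indent=2, sort_keys=True) + "\n")
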