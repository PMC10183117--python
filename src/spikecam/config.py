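"""Run configuration: one validated object for a whole pipeline run.

A ``RunConfig`` collects the knobs the CLI exposes as flags so batch runs
can be driven from a single YAML (or JSON — YAML is a superset) file::

    images_dir: data
    labels: data/labels.csv
    out_dir: out
    label_dialect: rows        # rows | packed
    upsample_method: bilinear  # bilinear | nearest
    mask_threshold: 0.0
    iou_threshold: 0.5
    zero_poor_pct: 25.0
    zero_excellent_pct: 20.0
    weight_seed: 0
    scene_seed: 0
    log_level: info
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    images_dir: Optional[Path] = None
    labels: Optional[Path] = None
    activations_dir: Optional[Path] = None
    out_dir: Path = Path("out")
    label_dialect: str = "rows"
    upsample_method: str = "bilinear"
    mask_threshold: float = 0.0
    bin_width: float = 0.1
    zero_poor_pct: float = 25.0
    zero_excellent_pct: float = 20.0
    iou_threshold: float = 0.5
    weight_seed: int = 0
    scene_seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        for name in ("images_dir", "labels", "activations_dir", "out_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if self.label_dialect not in ("rows", "packed"):
            raise ConfigurationError(f"unknown label_dialect {self.label_dialect!r}")
        if self.upsample_method not in ("bilinear", "nearest"):
            raise ConfigurationError(f"unknown upsample_method {self.upsample_method!r}")
        if self.mask_threshold < 0:
            raise ConfigurationError("mask_threshold must be >= 0")
        if self.bin_width != 0.1:
            raise ConfigurationError("only the standard 0.1 bin width is supported")
        if not 0.0 <= self.zero_excellent_pct <= self.zero_poor_pct <= 100.0:
            raise ConfigurationError("advisor thresholds out of order")
        if not 0.0 < self.iou_threshold < 1.0:
            raise ConfigurationError("iou_threshold must lie in (0, 1)")

    def validate_paths(self) -> None:
        """Check every configured input path resolves before a run starts."""
        for name in ("images_dir", "labels", "activations_dir"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} does not exist: {value}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**payload)
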