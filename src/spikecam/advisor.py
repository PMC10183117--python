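"""Rule-based layer-refinement advisor.

Turns per-layer attention-score statistics into architectural
recommendations for a three-scale detector:

* large-scale layer: remove it when its attention is poor, else keep;
* small-scale layer: when excellent, keep it and add a micro-scale
  companion head for very small objects; when poor, remove it; else keep;
* medium-scale layer: when excellent, enhance its feature extraction
  (more backbone fusion into that head); else keep.

"Poor" and "excellent" are classified on the zero-score proportion — the
fraction of labeled objects a layer ignores entirely — which is the single
statistic that separates a layer that attends loosely from one that fails
outright.  The thresholds (defaults: poor at >= 25%, excellent at <= 20%)
are explicit, configurable, and echoed in every report.  The advisor only
recommends; it never edits a network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError, InputError
from .layerstats import LayerScoreStats

__all__ = ["AdvisorThresholds", "RefinementAdvice", "classify_layer", "advise"]

VERDICTS = ("poor", "moderate", "excellent")
ACTIONS = ("remove", "keep", "enhance_features", "add_micro_scale_companion")


@dataclass(frozen=True)
class AdvisorThresholds:
    """Zero-score-proportion cutoffs, in percent.

    A layer is *poor* when its zero-score proportion is >= ``zero_poor_pct``
    (boundary inclusive) and *excellent* when <= ``zero_excellent_pct``;
    anything between is *moderate*.  When the two thresholds coincide the
    poor rule wins at the shared boundary.
    """

    zero_poor_pct: float = 25.0
    zero_excellent_pct: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_excellent_pct <= self.zero_poor_pct <= 100.0:
            raise ConfigurationError(
                "need 0 <= zero_excellent_pct <= zero_poor_pct <= 100, got "
                f"excellent={self.zero_excellent_pct}, poor={self.zero_poor_pct}"
            )


@dataclass
class RefinementAdvice:
    """Per-layer verdicts, actions and the statistics that decided them."""

    verdicts: dict[str, str]
    actions: dict[str, tuple[str, ...]]
    rationale: dict[str, str]
    thresholds: AdvisorThresholds = field(default_factory=AdvisorThresholds)

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "zero_poor_pct": self.thresholds.zero_poor_pct,
                "zero_excellent_pct": self.thresholds.zero_excellent_pct,
            },
            "layers": {
                layer: {
                    "verdict": self.verdicts[layer],
                    "actions": list(self.actions[layer]),
                    "rationale": self.rationale[layer],
                }
                for layer in self.verdicts
            },
        }

    def to_text(self) -> str:
        lines = [
            "refinement advice "
            f"(poor >= {self.thresholds.zero_poor_pct}% zero-score, "
            f"excellent <= {self.thresholds.zero_excellent_pct}%):"
        ]
        for layer in self.verdicts:
            acts = " + ".join(self.actions[layer])
            lines.append(f"  {layer}: {self.verdicts[layer]} -> {acts}")
            lines.append(f"      {self.rationale[layer]}")
        return "\n".join(lines)


def classify_layer(
    stats: LayerScoreStats, thresholds: AdvisorThresholds = AdvisorThresholds()
) -> str:
    """poor / moderate / excellent from the zero-score proportion."""
    if stats.zero_proportion_pct >= thresholds.zero_poor_pct:
        return "poor"
    if stats.zero_proportion_pct <= thresholds.zero_excellent_pct:
        return "excellent"
    return "moderate"


def _rationale(stats: LayerScoreStats, verdict: str) -> str:
    return (
        f"zero-score proportion {stats.zero_proportion_pct:.1f}%, "
        f"mean score {stats.mean_score:.3f}, "
        f"score range [{stats.score_min:.3f}, {stats.score_max:.3f}], "
        f"n={stats.n_records} -> {verdict}"
    )


def advise(
    stats: Sequence[LayerScoreStats],
    thresholds: AdvisorThresholds = AdvisorThresholds(),
) -> RefinementAdvice:
    """Map small/medium/large layer statistics to refinement actions."""
    by_layer = {s.layer_id: s for s in stats}
    missing = {"small", "medium", "large"} - set(by_layer)
    if missing:
        raise InputError(f"advisor needs small/medium/large stats; missing {sorted(missing)}")

    verdicts, actions, rationale = {}, {}, {}
    for layer in ("small", "medium", "large"):
        s = by_layer[layer]
        v = classify_layer(s, thresholds)
        verdicts[layer] = v
        rationale[layer] = _rationale(s, v)
        if layer == "large":
            actions[layer] = ("remove",) if v == "poor" else ("keep",)
        elif layer == "small":
            if v == "excellent":
                actions[layer] = ("keep", "add_micro_scale_companion")
            elif v == "poor":
                actions[layer] = ("remove",)
            else:
                actions[layer] = ("keep",)
        else:  # medium
            actions[layer] = ("enhance_features",) if v == "excellent" else ("keep",)
    return RefinementAdvice(
        verdicts=verdicts, actions=actions, rationale=rationale, thresholds=thresholds
    )
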