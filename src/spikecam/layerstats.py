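"""Per-layer attention-score statistics.

Aggregates attention-score records into the standard per-layer views used to
judge detection layers:

* a ten-bin table over [0, 1] in 0.1-wide score intervals (last bin closed at
  1.0) with the proportion of objects and their mean pixel size per bin;
* a zero-score audit — the proportion and mean size of objects a layer
  ignores entirely (S = 0);
* a one-line summary (score range, mean score) per layer;
* a ranking across layers, ascending by zero-score proportion with mean
  score as tie-break.

Zero-score objects appear both inside the first bin of the table and in the
separate audit; the two views deliberately overlap.  Proportions are
computed with exact rational arithmetic on counts so that they always sum to
100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .errors import InputError, StatisticsError
from .scoring import AttentionScoreRecord, layer_sort_key

__all__ = [
    "ScoreBin",
    "LayerScoreStats",
    "LayerRanking",
    "bin_scores",
    "zero_score_audit",
    "layer_summary",
    "compare_layers",
    "N_BINS",
]

N_BINS = 10

# Scores are ratios of small integers; this nudge keeps exact decimal
# boundaries (e.g. 3/10) in their mathematically correct bin despite binary
# floating point, and is far below the resolution of any realistic box area.
_BIN_EPS = 1e-9


@dataclass(frozen=True)
class ScoreBin:
    """One 0.1-wide score interval of a layer's bin table."""

    lower: float
    upper: float
    count: int
    proportion_pct: float
    mean_spike_size: Optional[float]  # None when the bin is empty

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise InputError(f"invalid bin bounds [{self.lower}, {self.upper}]")


@dataclass
class LayerScoreStats:
    """Complete per-layer score statistics (bin table + audit + summary)."""

    layer_id: str
    n_records: int
    bins: list[ScoreBin]
    score_min: float
    score_max: float
    mean_score: float
    zero_proportion_pct: float
    zero_mean_spike_size: Optional[float]
    zero_count: int = 0
    bin_counts: list[int] = field(default_factory=list)

    def proportion_fractions(self) -> list[Fraction]:
        """Exact bin proportions (in percent) as rationals; sums to 100."""
        return [Fraction(100 * c, self.n_records) for c in self.bin_counts]

    def display_rows(self) -> list[dict]:
        """Rows at table precision: proportions to 0.1%, sizes to 1 px."""
        rows = []
        for b in self.bins:
            rows.append(
                {
                    "layer_id": self.layer_id,
                    "score_range": f"{b.lower:.1f}-{b.upper:.1f}",
                    "proportion_pct": round(b.proportion_pct, 1),
                    "mean_spike_size": None
                    if b.mean_spike_size is None
                    else round(b.mean_spike_size),
                }
            )
        return rows


def _bin_index(score: float) -> int:
    """0.1-wide bins, half-open, except the last which is closed at 1.0."""
    return min(int(math.floor(score * N_BINS + _BIN_EPS)), N_BINS - 1)


def bin_scores(records: Sequence[AttentionScoreRecord]) -> list[ScoreBin]:
    """Tabulate one layer's records into the ten standard score bins."""
    if not records:
        raise StatisticsError("cannot bin an empty record list")
    counts = [0] * N_BINS
    size_sums = [0.0] * N_BINS
    for r in records:
        if not 0.0 <= r.score <= 1.0:
            raise InputError(f"score {r.score} outside [0, 1]")
        i = _bin_index(r.score)
        counts[i] += 1
        size_sums[i] += r.spike_size
    total = len(records)
    bins = []
    for i in range(N_BINS):
        bins.append(
            ScoreBin(
                lower=i / N_BINS,
                upper=(i + 1) / N_BINS,
                count=counts[i],
                proportion_pct=float(Fraction(100 * counts[i], total)),
                mean_spike_size=size_sums[i] / counts[i] if counts[i] else None,
            )
        )
    return bins


def zero_score_audit(
    records: Sequence[AttentionScoreRecord],
) -> tuple[float, Optional[float]]:
    """Proportion (%) and mean pixel size of records with S exactly 0."""
    if not records:
        raise StatisticsError("cannot audit an empty record list")
    zeros = [r for r in records if r.score == 0.0]
    proportion = float(Fraction(100 * len(zeros), len(records)))
    mean_size = sum(r.spike_size for r in zeros) / len(zeros) if zeros else None
    return proportion, mean_size


def layer_summary(
    records: Sequence[AttentionScoreRecord], layer_id: Optional[str] = None
) -> LayerScoreStats:
    """Assemble bins, score range, mean score and zero audit for one layer."""
    if not records:
        raise StatisticsError("cannot summarize an empty record list")
    ids = {r.layer_id for r in records}
    if layer_id is None:
        if len(ids) != 1:
            raise InputError(f"records span multiple layers {sorted(ids)}; pass layer_id")
        layer_id = next(iter(ids))
    scores = [r.score for r in records]
    bins = bin_scores(records)
    zero_pct, zero_size = zero_score_audit(records)
    return LayerScoreStats(
        layer_id=layer_id,
        n_records=len(records),
        bins=bins,
        score_min=min(scores),
        score_max=max(scores),
        mean_score=sum(scores) / len(scores),
        zero_proportion_pct=zero_pct,
        zero_mean_spike_size=zero_size,
        zero_count=sum(1 for s in scores if s == 0.0),
        bin_counts=[b.count for b in bins],
    )


@dataclass
class LayerRanking:
    """Layers ordered best to worst by the zero-score criterion."""

    ranking: list[LayerScoreStats]

    @property
    def best(self) -> LayerScoreStats:
        return self.ranking[0]

    @property
    def worst(self) -> LayerScoreStats:
        return self.ranking[-1]

    def to_text(self) -> str:
        lines = ["layer ranking (ascending zero-score proportion, mean score tie-break):"]
        for pos, s in enumerate(self.ranking, start=1):
            marks = ""
            if s is self.best:
                marks = "  <- best"
            elif s is self.worst:
                marks = "  <- worst"
            lines.append(
                f"  {pos}. {s.layer_id}: zero-score {s.zero_proportion_pct:.1f}%, "
                f"mean score {s.mean_score:.3f}, "
                f"range [{s.score_min:.3f}, {s.score_max:.3f}]{marks}"
            )
        return "\n".join(lines)


def compare_layers(stats: Sequence[LayerScoreStats]) -> LayerRanking:
    """Rank >= 2 layers: ascending zero-score proportion, then descending
    mean score, then canonical small -> medium -> large order."""
    if len(stats) < 2:
        raise InputError("need at least two layers to compare")
    ids = [s.layer_id for s in stats]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate layer ids in {ids}")
    ordered = sorted(
        stats,
        key=lambda s: (s.zero_proportion_pct, -s.mean_score, layer_sort_key(s.layer_id)),
    )
    return LayerRanking(ranking=ordered)
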