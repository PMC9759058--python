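"""Two-experiment analytics: offset alignment, slope/difference charts,
distribution summaries.

Two image series are compared after a user-supplied frame offset synchronizes
their respiratory cycles.  A slope chart contrasts a feature's mean over the
first vs. last complete cycle; distribution summaries back violin-style
plots; the per-cycle absolute-difference chart contrasts cycle means between
conditions at each aligned cycle index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import (FrameStats, RespiratoryCycle, detect_cycles,
                       feature_series)


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary plus mean of per-frame feature values."""

    min: float
    q25: float
    median: float
    q75: float
    max: float
    mean: float

    def __post_init__(self) -> None:
        if not self.min <= self.q25 <= self.median <= self.q75 <= self.max:
            raise ValueError("summary quantiles out of order")


@dataclass
class ComparisonResult:
    """All two-experiment comparison outputs for a set of features."""

    offset_frames: int
    slope_pairs: dict[str, dict[str, tuple[float, float]]]
    distribution_summaries: dict[str, dict[str, DistributionSummary]]
    cycle_differences: dict[str, list[float]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "offset_frames": self.offset_frames,
            "slope_pairs": {
                f: {exp: list(pair) for exp, pair in d.items()}
                for f, d in self.slope_pairs.items()
            },
            "distribution_summaries": {
                f: {exp: dataclasses.asdict(s) for exp, s in d.items()}
                for f, d in self.distribution_summaries.items()
            },
            "cycle_differences": self.cycle_differences,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return path


def apply_offset(series_b: Sequence[FrameStats], offset_frames: int
                 ) -> list[FrameStats]:
    """Shift a series in time by dropping frames; no resampling.

    Positive offsets drop leading frames, negative offsets drop trailing
    frames; remaining frames are re-indexed from 0.
    """
    n = len(series_b)
    if abs(offset_frames) >= n:
        raise ValueError(f"offset {offset_frames} exceeds series length {n}")
    if offset_frames >= 0:
        kept = series_b[offset_frames:]
    else:
        kept = series_b[:offset_frames]
    return [dataclasses.replace(s, frame_index=i) for i, s in enumerate(kept)]


def _cycle_mean(series, cycle: RespiratoryCycle, feature: str) -> float:
    vals = feature_series(series, feature)[cycle.start_frame:cycle.end_frame]
    return float(vals.mean())


def slope_chart(
    series: Sequence[FrameStats],
    cycles: Sequence[RespiratoryCycle],
    feature: str,
) -> tuple[float, float]:
    """(start, end) = feature mean over the first vs. last complete cycle."""
    if len(cycles) == 0:
        raise ValueError("slope chart requires at least one cycle")
    return (_cycle_mean(series, cycles[0], feature),
            _cycle_mean(series, cycles[-1], feature))


def distribution_summary(series: Sequence[FrameStats], feature: str
                         ) -> DistributionSummary:
    """Summary of the per-frame distribution; quantiles by linear interpolation."""
    if len(series) == 0:
        raise ValueError("empty series")
    vals = feature_series(series, feature)
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return DistributionSummary(
        min=float(vals.min()), q25=float(q25), median=float(med),
        q75=float(q75), max=float(vals.max()), mean=float(vals.mean()),
    )


def cycle_difference_chart(
    series_a: Sequence[FrameStats], cycles_a: Sequence[RespiratoryCycle],
    series_b: Sequence[FrameStats], cycles_b: Sequence[RespiratoryCycle],
    feature: str,
) -> list[float]:
    """|mean_A(k) - mean_B(k)| for each aligned cycle index k.

    Length is min(#cycles_A, #cycles_B); symmetric in its two series.
    """
    n = min(len(cycles_a), len(cycles_b))
    return [
        abs(_cycle_mean(series_a, cycles_a[k], feature)
            - _cycle_mean(series_b, cycles_b[k], feature))
        for k in range(n)
    ]


def estimate_offset(
    series_a: Sequence[FrameStats], series_b: Sequence[FrameStats],
    max_offset: int | None = None,
) -> int:
    """Automatic offset for B maximizing the cross-correlation of the two
    mean-centered alveolar-area signals (extension beyond the manual control).
    """
    a = feature_series(series_a, "alveolar_area_pct")
    b = feature_series(series_b, "alveolar_area_pct")
    a = a - a.mean()
    b = b - b.mean()
    if max_offset is None:
        max_offset = min(len(a), len(b)) // 2
    best_off, best_corr = 0, -np.inf
    for off in range(-max_offset, max_offset + 1):
        if off >= 0:
            bb, aa = b[off:], a
        else:
            bb, aa = b, a[-off:]
        m = min(len(aa), len(bb))
        if m < 2:
            continue
        corr = float(np.dot(aa[:m], bb[:m])) / m
        if corr > best_corr:
            best_corr, best_off = corr, off
    return best_off


def compare_experiments(
    series_a: Sequence[FrameStats],
    series_b: Sequence[FrameStats],
    offset_frames: int = 0,
    features: Sequence[str] = ("alveolar_area_pct", "neutrophil_area_pct"),
    cycle_params: dict | None = None,
) -> ComparisonResult:
    """Full two-experiment comparison after offsetting series B.

    Cycles are re-detected on the offset series; per-feature slope pairs,
    distribution summaries and per-cycle absolute differences are computed
    for both experiments (labeled ``"A"`` and ``"B"``).
    """
    cycle_params = cycle_params or {}
    series_b = apply_offset(series_b, offset_frames)
    cycles_a = detect_cycles(series_a, **cycle_params)
    cycles_b = detect_cycles(series_b, **cycle_params)
    slope: dict[str, dict[str, tuple[float, float]]] = {}
    dists: dict[str, dict[str, DistributionSummary]] = {}
    diffs: dict[str, list[float]] = {}
    for f in features:
        slope[f] = {"A": slope_chart(series_a, cycles_a, f),
                    "B": slope_chart(series_b, cycles_b, f)}
        dists[f] = {"A": distribution_summary(series_a, f),
                    "B": distribution_summary(series_b, f)}
        diffs[f] = cycle_difference_chart(series_a, cycles_a,
                                          series_b, cycles_b, f)
    return ComparisonResult(
        offset_frames=offset_frames, slope_pairs=slope,
        distribution_summaries=dists, cycle_differences=diffs,
    )


def plot_slope_chart(result: ComparisonResult, path) -> None:
    """Start-vs-end slope chart for every compared feature (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = list(result.slope_pairs)
    fig, axes = plt.subplots(1, len(feats), figsize=(3 * len(feats), 3),
                             squeeze=False)
    for ax, f in zip(axes[0], feats):
        for exp, (start, end) in result.slope_pairs[f].items():
            ax.plot([0, 1], [start, end], marker="o", label=exp)
        ax.set_xticks([0, 1], ["first cycle", "last cycle"])
        ax.set_title(f, fontsize=8)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_difference_chart(result: ComparisonResult, path) -> None:
    """Per-cycle absolute-difference lines for every compared feature (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    for f, d in result.cycle_differences.items():
        ax.plot(d, marker=".", lw=1, label=f)
    ax.set_xlabel("aligned cycle index")
    ax.set_ylabel("|mean A - mean B|")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
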