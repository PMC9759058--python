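"""Per-frame scalar features and respiratory-cycle analytics.

Each frame reduces to a handful of scalars: total alveolar airspace as a
percentage of image area, alveolus count, airspace per alveolus, neutrophil
count and area, and interstitial (dextran-bright) area.  Breathing makes the
alveolar-area signal oscillate; cycles are delimited at end-expiration
troughs of the smoothed signal, so each cycle rises through inspiration and
falls back, like the volume-time curves on a ventilator display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .segmentation import Contour


@dataclass(frozen=True)
class FrameStats:
    """Scalar features of one frame; percentages are of total image area."""

    frame_index: int
    alveolar_area_pct: float
    alveoli_count: int
    airspace_per_alveolus_pct: float
    neutrophil_count: int
    neutrophil_area_pct: float
    interstitial_area_pct: float

    def __post_init__(self) -> None:
        for name in ("alveolar_area_pct", "neutrophil_area_pct",
                     "interstitial_area_pct", "airspace_per_alveolus_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.alveoli_count < 0 or self.neutrophil_count < 0:
            raise ValueError("counts must be >= 0")


#: FrameStats field names usable as a comparison/summary feature.
FEATURE_NAMES = (
    "alveolar_area_pct",
    "alveoli_count",
    "airspace_per_alveolus_pct",
    "neutrophil_count",
    "neutrophil_area_pct",
    "interstitial_area_pct",
)


@dataclass(frozen=True)
class RespiratoryCycle:
    """One trough-to-trough breathing cycle.

    ``start_frame`` inclusive, ``end_frame`` exclusive; consecutive cycles
    tile the covered frame range.  Extremes are taken from the raw
    (unsmoothed) alveolar-area signal within the span.
    """

    cycle_index: int
    start_frame: int
    end_frame: int
    min_alveolar_pct: float
    max_alveolar_pct: float

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must precede end_frame")
        if self.min_alveolar_pct > self.max_alveolar_pct:
            raise ValueError("cycle min exceeds max")

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def amplitude(self) -> float:
        return self.max_alveolar_pct - self.min_alveolar_pct


@dataclass(frozen=True)
class ExperimentSummary:
    """Kiviat (radar) axes summarizing one experiment.

    ``mean_cycle_amplitude`` and ``mean_cycle_length`` are ``None`` when no
    complete cycle was detected.
    """

    mean_alveolar_area_pct: float
    mean_cycle_amplitude: float | None
    mean_alveoli_count: float
    mean_neutrophil_count: float
    mean_neutrophil_area_pct: float
    mean_cycle_length: float | None

    AXES = ("mean_alveolar_area_pct", "mean_cycle_amplitude",
            "mean_alveoli_count", "mean_neutrophil_count",
            "mean_neutrophil_area_pct", "mean_cycle_length")

    def as_dict(self) -> dict[str, float | None]:
        return {a: getattr(self, a) for a in self.AXES}


def feature_series(series: Sequence[FrameStats], feature: str) -> np.ndarray:
    """Per-frame values of one named feature as a float array."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}; one of {FEATURE_NAMES}")
    return np.array([getattr(s, feature) for s in series], dtype=float)


def compute_frame_stats(
    alveoli: Sequence[Contour],
    neutrophils: Sequence[Contour],
    interstitial_mask: np.ndarray | None,
    dims: tuple[int, int],
    frame_index: int = 0,
) -> FrameStats:
    """Reduce one frame's detections to scalar features.

    ``interstitial_mask`` is the bright-polarity mask of the interstitial
    channel (may be ``None`` -> interstitial area 0).  Percentages are of
    ``dims`` image area; ``airspace_per_alveolus_pct`` is the alveolar area
    percentage divided by the per-frame alveolus count (0 when no alveoli).
    """
    h, w = dims
    if h <= 0 or w <= 0:
        raise ValueError("image dimensions must be positive")
    total = float(h * w)
    alv_area = sum(c.area for c in alveoli)
    neu_area = sum(c.area for c in neutrophils)
    alv_pct = min(100.0, 100.0 * alv_area / total)
    neu_pct = min(100.0, 100.0 * neu_area / total)
    if interstitial_mask is not None:
        int_pct = 100.0 * float(np.count_nonzero(interstitial_mask)) / total
    else:
        int_pct = 0.0
    n_alv = len(alveoli)
    return FrameStats(
        frame_index=frame_index,
        alveolar_area_pct=alv_pct,
        alveoli_count=n_alv,
        airspace_per_alveolus_pct=alv_pct / n_alv if n_alv else 0.0,
        neutrophil_count=len(neutrophils),
        neutrophil_area_pct=neu_pct,
        interstitial_area_pct=min(100.0, int_pct),
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; window clipped near the edges."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_cycles(
    series: Sequence[FrameStats],
    smoothing_window: int = 3,
    min_cycle_len: int = 4,
    prominence: float = 0.5,
) -> list[RespiratoryCycle]:
    """Segment the alveolar-area signal into trough-to-trough cycles.

    The signal is smoothed by a centered moving average; troughs are local
    minima with at least ``prominence`` percentage points of prominence and
    ``min_cycle_len`` frames of separation.  Cycle ``k`` spans
    ``[trough_k, trough_{k+1})``; min/max come from the unsmoothed signal.
    Frames before the first or after the last trough belong to no cycle.

    Raises
    ------
    ValueError
        If fewer than two troughs are found ("no complete respiratory cycle
        detected").
    """
    raw = feature_series(series, "alveolar_area_pct")
    if len(raw) < 2 * min_cycle_len:
        raise ValueError("series too short for cycle detection")
    smooth = _moving_average(raw, smoothing_window)
    troughs, _ = find_peaks(-smooth, prominence=prominence,
                            distance=max(1, min_cycle_len))
    if len(troughs) < 2:
        raise ValueError("no complete respiratory cycle detected")
    cycles = []
    for k in range(len(troughs) - 1):
        a, b = int(troughs[k]), int(troughs[k + 1])
        span = raw[a:b]
        cycles.append(RespiratoryCycle(
            cycle_index=k, start_frame=a, end_frame=b,
            min_alveolar_pct=float(span.min()),
            max_alveolar_pct=float(span.max()),
        ))
    return cycles


def cycle_overlay(
    series: Sequence[FrameStats], cycles: Sequence[RespiratoryCycle]
) -> list[np.ndarray]:
    """Per-cycle alveolar-area traces re-indexed to cycle-relative phase.

    Trace ``k`` is the raw signal over cycle ``k``; index 0 is the cycle's
    start frame.  Suitable for overlaying tidal breaths on one axis.
    """
    raw = feature_series(series, "alveolar_area_pct")
    return [raw[c.start_frame:c.end_frame].copy() for c in cycles]


def summarize_experiment(
    series: Sequence[FrameStats], cycles: Sequence[RespiratoryCycle]
) -> ExperimentSummary:
    """Kiviat-axis summary: feature means plus per-cycle amplitude/length."""
    if len(series) == 0:
        raise ValueError("empty series")
    if cycles:
        amp = float(np.mean([c.amplitude for c in cycles]))
        clen = float(np.mean([c.length for c in cycles]))
    else:
        amp = clen = None
    return ExperimentSummary(
        mean_alveolar_area_pct=float(np.mean(feature_series(series, "alveolar_area_pct"))),
        mean_cycle_amplitude=amp,
        mean_alveoli_count=float(np.mean(feature_series(series, "alveoli_count"))),
        mean_neutrophil_count=float(np.mean(feature_series(series, "neutrophil_count"))),
        mean_neutrophil_area_pct=float(np.mean(feature_series(series, "neutrophil_area_pct"))),
        mean_cycle_length=clen,
    )


def normalize_summaries(
    summaries: Sequence[ExperimentSummary],
) -> list[dict[str, float | None]]:
    """Min-max normalize each Kiviat axis to [0, 1] across experiments.

    Axes constant across experiments map to 0.5; absent values stay ``None``.
    """
    out: list[dict[str, float | None]] = [dict() for _ in summaries]
    for axis in ExperimentSummary.AXES:
        vals = [getattr(s, axis) for s in summaries]
        present = [v for v in vals if v is not None]
        lo = min(present) if present else 0.0
        hi = max(present) if present else 0.0
        for d, v in zip(out, vals):
            if v is None:
                d[axis] = None
            elif hi == lo:
                d[axis] = 0.5
            else:
                d[axis] = (v - lo) / (hi - lo)
    return out


# -- static plots (Fig-5/6-style panels) ------------------------------------

def plot_timeline(series, cycles, path) -> None:
    """Alveolar-area timeline with the per-cycle min/max band (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    raw = feature_series(series, "alveolar_area_pct")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(raw, lw=1, color="tab:blue", label="alveolar area %")
    for c in cycles:
        ax.fill_between([c.start_frame, c.end_frame - 1],
                        c.min_alveolar_pct, c.max_alveolar_pct,
                        alpha=0.15, color="tab:blue")
        ax.axvline(c.start_frame, color="gray", lw=0.5, ls=":")
    ax.set_xlabel("frame")
    ax.set_ylabel("alveolar area (% of image)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_cycle_overlay(series, cycles, path) -> None:
    """Overlaid respiratory-cycle traces (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traces = cycle_overlay(series, cycles)
    fig, ax = plt.subplots(figsize=(4, 3))
    for k, tr in enumerate(traces):
        ax.plot(tr, lw=1, alpha=0.8, label=f"cycle {k}")
    ax.set_xlabel("frame offset within cycle")
    ax.set_ylabel("alveolar area (% of image)")
    if len(traces) <= 6:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_feature_charts(series, path) -> None:
    """Per-frame charts of every scalar feature, stacked (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(FEATURE_NAMES), 1,
                             figsize=(8, 1.6 * len(FEATURE_NAMES)),
                             sharex=True)
    for ax, name in zip(axes, FEATURE_NAMES):
        ax.plot(feature_series(series, name), lw=1)
        ax.set_ylabel(name, fontsize=7)
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_kiviat(summaries, labels, path) -> None:
    """Radar chart of normalized experiment summaries (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = normalize_summaries(summaries)
    axes_names = ExperimentSummary.AXES
    angles = np.linspace(0, 2 * np.pi, len(axes_names), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    for d, label in zip(norm, labels):
        vals = np.array([d[a] if d[a] is not None else 0.0 for a in axes_names])
        closed = np.concatenate([vals, vals[:1]])
        ang = np.concatenate([angles, angles[:1]])
        ax.plot(ang, closed, lw=1, label=label)
        ax.fill(ang, closed, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(axes_names, fontsize=6)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
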