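"""End-to-end single-experiment pipeline.

Chains the stages in running order — denoise, mask, segment, area-filter,
temporal-consistency filter, per-frame statistics, cycle detection — for one
two-channel image series.  Both the command-line interface and the synthetic
recovery experiments drive this entry point, so every consumer exercises the
same code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .features import (FrameStats, RespiratoryCycle, compute_frame_stats,
                       detect_cycles)
from .imaging_io import ChannelRole, ChannelSeries
from .preprocess import (Polarity, PreprocessParams, default_params,
                         denoise_nlm, feature_mask, preprocess_series)
from .segmentation import (AreaRestriction, Contour, default_area_restriction,
                           segment_series)
from .tracking import (Rejection, TrackPolicy, default_track_policy,
                       filter_by_temporal_consistency)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces, stage by stage."""

    alveoli_masks: np.ndarray
    neutrophil_masks: np.ndarray
    interstitial_masks: np.ndarray
    raw_alveoli: list[list[Contour]]
    raw_neutrophils: list[list[Contour]]
    alveoli: list[list[Contour]]
    neutrophils: list[list[Contour]]
    rejections: list[Rejection]
    stats: list[FrameStats]
    cycles: list[RespiratoryCycle]


def run_pipeline(
    interstitial: ChannelSeries,
    neutrophil: ChannelSeries,
    *,
    alveoli_params: PreprocessParams | None = None,
    neutrophil_params: PreprocessParams | None = None,
    alveoli_restriction: AreaRestriction | None = None,
    neutrophil_restriction: AreaRestriction | None = None,
    alveoli_policy: TrackPolicy | None = None,
    neutrophil_policy: TrackPolicy | None = None,
    cycle_params: dict | None = None,
    detect_cycles_on_output: bool = True,
) -> PipelineResult:
    """Run preprocess -> segment -> track -> features -> cycles.

    Any parameter left ``None`` takes the role's documented default.  Cycle
    detection failures are surfaced as an empty ``cycles`` list when
    ``detect_cycles_on_output`` is False is not set; callers who must
    distinguish "no cycles" from errors can call
    :func:`alveotrack.features.detect_cycles` themselves.
    """
    if (interstitial.n_frames != neutrophil.n_frames
            or interstitial.frames.shape[1:] != neutrophil.frames.shape[1:]):
        raise ValueError("channel series not aligned")
    alveoli_params = alveoli_params or default_params(ChannelRole.INTERSTITIAL)
    neutrophil_params = neutrophil_params or default_params(ChannelRole.NEUTROPHIL)
    alveoli_restriction = alveoli_restriction or default_area_restriction(
        ChannelRole.INTERSTITIAL)
    neutrophil_restriction = neutrophil_restriction or default_area_restriction(
        ChannelRole.NEUTROPHIL)
    alveoli_policy = alveoli_policy or default_track_policy(ChannelRole.INTERSTITIAL)
    neutrophil_policy = neutrophil_policy or default_track_policy(ChannelRole.NEUTROPHIL)

    # denoise each channel once; the interstitial channel feeds two masks
    # (dark polarity -> alveoli, bright polarity -> interstitial area)
    bright = dataclasses.replace(alveoli_params,
                                 polarity=Polarity.BRIGHT_FEATURES)
    denoised_i = [denoise_nlm(f, alveoli_params) for f in interstitial.frames]
    alv_masks = np.stack([feature_mask(f, alveoli_params) for f in denoised_i])
    int_masks = np.stack([feature_mask(f, bright) for f in denoised_i])
    neu_masks = preprocess_series(neutrophil.frames, neutrophil_params)

    raw_alv = segment_series(alv_masks, ChannelRole.INTERSTITIAL,
                             alveoli_restriction)
    raw_neu = segment_series(neu_masks, ChannelRole.NEUTROPHIL,
                             neutrophil_restriction)
    rejections: list[Rejection] = []
    alv = filter_by_temporal_consistency(raw_alv, alveoli_policy, rejections)
    neu = filter_by_temporal_consistency(raw_neu, neutrophil_policy, rejections)

    dims = (interstitial.height, interstitial.width)
    stats = [
        compute_frame_stats(alv[t], neu[t], int_masks[t], dims, frame_index=t)
        for t in range(interstitial.n_frames)
    ]
    cycles: list[RespiratoryCycle] = []
    if detect_cycles_on_output:
        try:
            cycles = detect_cycles(stats)
        except ValueError:
            cycles = []
    return PipelineResult(
        alveoli_masks=alv_masks, neutrophil_masks=neu_masks,
        interstitial_masks=int_masks, raw_alveoli=raw_alv,
        raw_neutrophils=raw_neu, alveoli=alv, neutrophils=neu,
        rejections=rejections, stats=stats, cycles=cycles,
    )
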