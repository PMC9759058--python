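"""Temporal-consistency filtering of per-frame detections.

Static segmentation of noisy intravital video produces spurious one-frame
detections.  The filter here exploits the temporal structure of the data: a
detection at frame ``t`` is valid only if a matching feature (close centroid,
agreeing area) exists in at least one neighboring frame (``t-1`` or ``t+1``).
Alveoli deform with breathing, so their area match is relative; neutrophils
are rigid blobs and use a fixed absolute tolerance.

The filter is a single pass judged against the ORIGINAL neighbor detections,
which makes it deterministic and order-independent across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .imaging_io import ChannelRole
from .segmentation import Contour


@dataclass(frozen=True)
class TrackPolicy:
    """Matching tolerances for the temporal-consistency filter.

    Attributes
    ----------
    role
        Channel the policy applies to; selects the area criterion.
    area_tolerance_rel
        Alveoli: allowed relative area change between matched features, as a
        fraction of the larger area.  Breathing deformation is large, so the
        default is 0.5.
    area_tolerance_abs
        Neutrophils: fixed absolute area tolerance in px^2 (default 50).
    centroid_radius
        Maximum centroid displacement for a match, px.
    """

    role: ChannelRole
    area_tolerance_rel: float = 0.5
    area_tolerance_abs: float = 50.0
    centroid_radius: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", ChannelRole(self.role))
        if not 0 < self.area_tolerance_rel <= 1:
            raise ValueError("area_tolerance_rel must be in (0, 1]")
        if self.area_tolerance_abs < 0:
            raise ValueError("area_tolerance_abs must be >= 0")
        if self.centroid_radius <= 0:
            raise ValueError("centroid_radius must be > 0")


def default_track_policy(role: ChannelRole | str) -> TrackPolicy:
    """Default policies: alveoli radius 20 px / rel 0.5; neutrophils
    radius 15 px / abs 50 px^2."""
    role = ChannelRole(role)
    if role is ChannelRole.INTERSTITIAL:
        return TrackPolicy(role=role, centroid_radius=20.0)
    return TrackPolicy(role=role, centroid_radius=15.0)


def features_match(a: Contour, b: Contour, policy: TrackPolicy) -> bool:
    """True iff centroids are within ``centroid_radius`` AND areas agree.

    Alveoli (interstitial role): ``|area_a - area_b| <= rel_tol * max(areas)``.
    Neutrophils: ``|area_a - area_b| <= abs_tol``.
    """
    if a.role != b.role:
        raise ValueError(f"role mismatch: {a.role.value} vs {b.role.value}")
    if a.centroid_distance(b) > policy.centroid_radius:
        return False
    diff = abs(a.area - b.area)
    if policy.role is ChannelRole.INTERSTITIAL:
        return diff <= policy.area_tolerance_rel * max(a.area, b.area)
    return diff <= policy.area_tolerance_abs


@dataclass
class Rejection:
    """Audit record for one discarded detection."""

    frame_index: int
    centroid: tuple[float, float]
    area: float
    reason: str


def filter_by_temporal_consistency(
    detections: Sequence[Sequence[Contour]],
    policy: TrackPolicy,
    rejections: list[Rejection] | None = None,
) -> list[list[Contour]]:
    """Keep a contour at frame ``t`` iff it matches some UNFILTERED contour
    at frame ``t-1`` or ``t+1``.

    The first frame checks only ``t+1`` and the last only ``t-1``.  A single
    pass over the original detections, so removing one transient never
    invalidates another frame's features.  Optionally appends a
    :class:`Rejection` per discarded contour for auditability.
    """
    n = len(detections)
    if n < 2:
        raise ValueError("temporal filter requires >=2 frames")
    out: list[list[Contour]] = []
    for t, frame in enumerate(detections):
        kept = []
        for c in frame:
            neighbors = []
            if t > 0:
                neighbors.extend(detections[t - 1])
            if t < n - 1:
                neighbors.extend(detections[t + 1])
            if any(features_match(c, other, policy) for other in neighbors):
                kept.append(c)
            elif rejections is not None:
                rejections.append(Rejection(
                    frame_index=t, centroid=c.centroid, area=c.area,
                    reason="no matching feature in neighboring frames",
                ))
        out.append(kept)
    return out


# -- optional extension: persistent track identities ------------------------
#
# The temporal filter is existential and assigns no identities.  For
# trajectory-level analyses a greedy nearest-centroid linker is provided; it
# goes beyond the validity filter above and is not used by the core pipeline.

def link_tracks(
    detections: Sequence[Sequence[Contour]], policy: TrackPolicy
) -> list[list[int]]:
    """Greedy nearest-centroid track linking (extension).

    Returns per-frame lists of track ids parallel to ``detections``.  Each
    contour links to the closest unclaimed matching contour of the previous
    frame, else starts a new track.
    """
    next_id = 0
    ids: list[list[int]] = []
    for t, frame in enumerate(detections):
        frame_ids: list[int] = []
        claimed: set[int] = set()
        for c in frame:
            best_j, best_d = -1, float("inf")
            if t > 0:
                for j, prev in enumerate(detections[t - 1]):
                    if j in claimed or not features_match(c, prev, policy):
                        continue
                    d = c.centroid_distance(prev)
                    if d < best_d:
                        best_j, best_d = j, d
            if best_j >= 0:
                frame_ids.append(ids[t - 1][best_j])
                claimed.add(best_j)
            else:
                frame_ids.append(next_id)
                next_id += 1
        ids.append(frame_ids)
    return ids
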