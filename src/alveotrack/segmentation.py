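"""Contour extraction from binary masks and area filtering.

A "contour" here is the external boundary of one 8-connected foreground
component, with the component's filled pixel count as its area and the mean
of its foreground pixel coordinates as its centroid.  Holes inside a
component are ignored.  Per-channel area restrictions then discard
implausibly small or large detections (false positives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging_io import ChannelRole


@dataclass(frozen=True)
class Contour:
    """One detected feature in one frame.

    ``polygon`` is the traced external boundary as (x, y) vertices in image
    coordinates (x = column, y = row, 0-based, clockwise); ``area`` is the
    filled pixel count of the component, not the polygon area; ``centroid``
    is the (x, y) mean of the component's foreground pixels.
    """

    polygon: tuple[tuple[float, float], ...]
    area: float
    centroid: tuple[float, float]
    role: ChannelRole
    frame_index: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("contour area must be > 0")
        if len(self.polygon) < 3:
            raise ValueError("polygon must have >= 3 vertices")

    def centroid_distance(self, other: "Contour") -> float:
        return math.hypot(self.centroid[0] - other.centroid[0],
                          self.centroid[1] - other.centroid[1])


@dataclass(frozen=True)
class AreaRestriction:
    """Closed interval of acceptable contour areas in px^2.

    ``max_area=None`` means unbounded above.  Defaults (at 512x512 scale):
    alveoli [200, 26000], neutrophils [30, 800].
    """

    min_area: float
    max_area: float | None = None

    def __post_init__(self) -> None:
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")

    def admits(self, area: float) -> bool:
        if area < self.min_area:
            return False
        return self.max_area is None or area <= self.max_area


def default_area_restriction(role: ChannelRole | str) -> AreaRestriction:
    """Default per-channel area bounds, sized to typical feature scales."""
    role = ChannelRole(role)
    if role is ChannelRole.INTERSTITIAL:
        return AreaRestriction(200, 26000)
    return AreaRestriction(30, 800)


_EIGHT = np.ones((3, 3), bool)


def _boundary_polygon(component: np.ndarray, y0: int, x0: int) -> tuple:
    """External boundary of a component mask via sub-pixel iso-contouring.

    The component is padded so the traced contour is always closed; vertices
    are returned as (x, y) in the full-image frame, clockwise in image
    coordinates (y down).
    """
    padded = np.pad(component.astype(float), 1)
    # high connectivity keeps 8-connected (diagonal) components on one ring
    rings = measure.find_contours(padded, 0.5, fully_connected="high")
    # the external boundary is the longest ring (holes trace shorter ones)
    ring = max(rings, key=lambda r: len(r))
    verts = [(float(c - 1 + x0), float(r - 1 + y0)) for r, c in ring]
    if verts[0] == verts[-1]:
        verts = verts[:-1]
    # find_contours orients counter-clockwise with y up == clockwise on
    # screen, matching the documented convention; keep as-is
    return tuple(verts)


def extract_contours(
    mask: np.ndarray, role: ChannelRole | str, frame_index: int
) -> list[Contour]:
    """One :class:`Contour` per 8-connected foreground component of ``mask``.

    Components are emitted in scanline order of their first pixel.  An empty
    mask yields an empty list.
    """
    role = ChannelRole(role)
    mask = np.asarray(mask) > 0
    labels, n = ndimage.label(mask, structure=_EIGHT)
    contours: list[Contour] = []
    if n == 0:
        return contours
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        comp = labels[sl] == lab
        area = int(comp.sum())
        ys, xs = np.nonzero(comp)
        y0, x0 = sl[0].start, sl[1].start
        centroid = (float(xs.mean() + x0), float(ys.mean() + y0))
        polygon = _boundary_polygon(comp, y0, x0)
        contours.append(Contour(polygon=polygon, area=float(area),
                                centroid=centroid, role=role,
                                frame_index=frame_index))
    return contours


def apply_area_restriction(
    contours: Sequence[Contour], restriction: AreaRestriction
) -> list[Contour]:
    """Keep exactly the contours whose area lies within ``restriction``.

    Pure filter: order preserved, no contour mutated; idempotent.
    """
    return [c for c in contours if restriction.admits(c.area)]


def segment_series(
    masks: np.ndarray,
    role: ChannelRole | str,
    restriction: AreaRestriction | None = None,
) -> list[list[Contour]]:
    """Extract and area-filter contours for every frame of a mask stack."""
    role = ChannelRole(role)
    if restriction is None:
        restriction = default_area_restriction(role)
    return [
        apply_area_restriction(extract_contours(m, role, i), restriction)
        for i, m in enumerate(masks)
    ]
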