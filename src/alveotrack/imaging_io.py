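"""Image-sequence I/O and channel compositing.

Intravital lung microscopy acquisitions arrive as two parallel directories of
numbered single-channel frames: an *interstitial* channel (fluorescent-dextran
bright interstitium, dark alveolar airspaces) and a *neutrophil* channel
(bright labeled leukocytes on a dark background).  This module reads those
sequences into :class:`ChannelSeries` containers, composites the two channels
into RGB frames (interstitium blue, neutrophils red), and serializes per-frame
feature tables to CSV/JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .features import FrameStats


class ChannelRole(str, Enum):
    """Which anatomical feature a grayscale channel encodes."""

    INTERSTITIAL = "interstitial"
    NEUTROPHIL = "neutrophil"


#: Fixed column order of the per-frame feature table (CSV and JSON exports).
FEATURE_TABLE_COLUMNS = (
    "frame_index",
    "alveolar_area_pct",
    "alveoli_count",
    "airspace_per_alveolus_pct",
    "neutrophil_count",
    "neutrophil_area_pct",
    "interstitial_area_pct",
)

_INT_RUN = re.compile(r"\d+")


@dataclass
class ChannelSeries:
    """An ordered stack of 8-bit grayscale frames for one labeled channel.

    Parameters
    ----------
    role
        Which feature the channel encodes.
    frames
        ``(n_frames, height, width)`` uint8 array.
    frame_rate
        Optional acquisition rate in frames/second; metadata only.
    """

    role: ChannelRole
    frames: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, h, w) stack")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8)")
        self.role = ChannelRole(self.role)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)


def _frame_index(path: Path) -> int:
    """Frame index = first integer run in the filename stem.

    Raw microscopy exports commonly use unpadded counters (``f_2.tif``,
    ``f_10.tif``), so lexicographic order is wrong; the parsed integer is
    authoritative.
    """
    m = _INT_RUN.search(path.stem)
    if m is None:
        raise ValueError(f"no frame index in filename: {path.name}")
    return int(m.group())


def _read_gray(path: Path, collapse_rgb: bool, rescale_16bit: bool) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        if not collapse_rgb:
            raise ValueError(
                f"{path.name}: multi-channel image; pass collapse_rgb=True "
                "to average channels"
            )
        img = img.astype(np.float64).mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image")
    if img.dtype == np.uint8:
        return img
    if np.issubdtype(img.dtype, np.integer) and img.dtype.itemsize > 1:
        if not rescale_16bit:
            raise ValueError(
                f"{path.name}: >8-bit image; pass rescale_16bit=True to rescale"
            )
        img = img.astype(np.float64)
        mx = img.max()
        img = img * (255.0 / mx) if mx > 0 else img
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def load_channel_series(
    directory: str | Path,
    role: ChannelRole | str,
    pattern: str = "*",
    *,
    collapse_rgb: bool = False,
    rescale_16bit: bool = False,
    frame_rate: float | None = None,
) -> ChannelSeries:
    """Load a directory of numbered grayscale frames as a :class:`ChannelSeries`.

    Frames are ordered by the first integer run in each filename, not
    lexicographically.  All frames must share identical dimensions.

    Raises
    ------
    FileNotFoundError
        If no frames match ``pattern`` ("no frames found").
    ValueError
        On duplicate frame indices ("ambiguous frame order") or mismatched
        dimensions ("inconsistent frame geometry").
    """
    directory = Path(directory)
    paths = [p for p in directory.glob(pattern) if p.is_file()]
    if not paths:
        raise FileNotFoundError(f"no frames found in {directory} matching {pattern!r}")
    indexed = sorted((_frame_index(p), p) for p in paths)
    indices = [i for i, _ in indexed]
    if len(set(indices)) != len(indices):
        dup = next(i for i in indices if indices.count(i) > 1)
        raise ValueError(f"ambiguous frame order: duplicate frame index {dup}")
    frames = []
    shape: tuple[int, int] | None = None
    for _, p in indexed:
        img = _read_gray(p, collapse_rgb, rescale_16bit)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"inconsistent frame geometry: {p.name} is {img.shape}, "
                f"expected {shape}"
            )
        frames.append(img)
    return ChannelSeries(
        role=ChannelRole(role), frames=np.stack(frames), frame_rate=frame_rate
    )


def save_channel_series(series: ChannelSeries, directory: str | Path,
                        prefix: str = "frame", fmt: str = "png") -> list[Path]:
    """Write each frame of ``series`` as ``<prefix>_<0-padded index>.<fmt>``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pad = max(4, len(str(series.n_frames - 1)))
    paths = []
    for i, frame in enumerate(series):
        path = directory / f"{prefix}_{i:0{pad}d}.{fmt}"
        if fmt in {"tif", "tiff"}:
            tifffile.imwrite(path, frame)
        else:
            iio.imwrite(path, frame)
        paths.append(path)
    return paths


def combine_channels(
    interstitial: ChannelSeries, neutrophil: ChannelSeries
) -> np.ndarray:
    """Composite the two channels into RGB frames.

    The interstitial channel fills the blue plane and the neutrophil channel
    the red plane; green is reserved all-zero.  The mapping is lossless: the
    blue and red planes of the output reconstruct the inputs exactly.

    Returns
    -------
    ``(n_frames, height, width, 3)`` uint8 array.
    """
    if (interstitial.n_frames != neutrophil.n_frames
            or interstitial.frames.shape[1:] != neutrophil.frames.shape[1:]):
        raise ValueError("channel series not aligned")
    n, h, w = interstitial.frames.shape
    rgb = np.zeros((n, h, w, 3), dtype=np.uint8)
    rgb[..., 0] = neutrophil.frames
    rgb[..., 2] = interstitial.frames
    return rgb


def split_composite(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`combine_channels`: (interstitial, neutrophil) stacks."""
    rgb = np.asarray(rgb)
    return rgb[..., 2].copy(), rgb[..., 0].copy()


def write_composite_frames(rgb: np.ndarray, directory: str | Path,
                           prefix: str = "composite") -> list[Path]:
    """Write RGB composite frames as numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pad = max(4, len(str(len(rgb) - 1)))
    paths = []
    for i, frame in enumerate(rgb):
        path = directory / f"{prefix}_{i:0{pad}d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def write_feature_table(stats: Sequence["FrameStats"], path: str | Path) -> Path:
    """Serialize per-frame statistics as CSV plus a parallel ``.json`` export.

    The CSV holds one row per frame in :data:`FEATURE_TABLE_COLUMNS` order;
    the JSON file (same stem, ``.json`` suffix) holds one object per frame
    with the same fields, for front-end consumption.  Round-tripping through
    :func:`read_feature_table` preserves values to better than 6 decimals.
    """
    if len(stats) == 0:
        raise ValueError("cannot write an empty feature table")
    path = Path(path)
    rows = [{c: getattr(s, c) for c in FEATURE_TABLE_COLUMNS} for s in stats]
    df = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(rows, fh, indent=1)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV back into a DataFrame in canonical column order."""
    df = pd.read_csv(path)
    return df[list(FEATURE_TABLE_COLUMNS)]


def write_contours_json(per_frame_contours, path: str | Path) -> Path:
    """Export per-frame contours (polygon, area, centroid, role) as JSON."""
    path = Path(path)
    doc = [
        [
            {
                "frame_index": c.frame_index,
                "role": c.role.value,
                "area": float(c.area),
                "centroid": [float(c.centroid[0]), float(c.centroid[1])],
                "polygon": [[float(x), float(y)] for x, y in c.polygon],
            }
            for c in frame
        ]
        for frame in per_frame_contours
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path
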