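"""Stack projection, robust normalisation, and classical somitoid segmentation.

Segmentation here is a deliberately simple classical stand-in (Otsu ->
opening -> largest component -> hole filling): deep-learning masks produced
elsewhere can be supplied as external masks and override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening


class SegmentationEmptyError(RuntimeError):
    """Raised when thresholding leaves no foreground to segment."""


@dataclass
class Movie:
    """A time-lapse fluorescence recording.

    ``data`` is ``(t, y, x)`` or ``(t, z, y, x)``; intensities are
    non-negative arbitrary units. ``frame_interval_min`` is the time between
    consecutive frames in minutes.
    """

    data: np.ndarray
    frame_interval_min: float
    pixel_size: float = 1.0
    channel: Literal["reporter", "brightfield"] = "reporter"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("Movie.data must be (t, y, x) or (t, z, y, x)")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_min)


@dataclass
class Mask:
    """A binary somitoid mask with provenance."""

    data: np.ndarray
    source: Literal["builtin", "external"] = "builtin"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("Mask.data must be 2D")
        if not self.data.any():
            raise ValueError("Mask is empty")


def project_stack(movie: Movie, mode: Literal["max", "mean"] = "max") -> Movie:
    """Project the z dimension out of a ``(t, z, y, x)`` movie.

    A movie that is already ``(t, y, x)`` is returned unchanged (identity).
    """
    if movie.data.size == 0:
        raise ValueError("empty stack")
    if not movie.has_z:
        return movie
    if mode == "max":
        proj = movie.data.max(axis=1)
    elif mode == "mean":
        proj = movie.data.mean(axis=1)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return replace(movie, data=proj)


def normalize_plane(frame: np.ndarray) -> np.ndarray:
    """Robust min-max scaling of one 2D frame to [0, 1].

    Uses the 1st and 99th intensity percentiles so isolated hot pixels do not
    set the scale; output is clipped to [0, 1]. A constant frame yields zeros
    with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = np.percentile(frame, [1.0, 99.0])
    if hi <= lo:
        warnings.warn("constant frame: normalization returns zeros", stacklevel=2)
        return np.zeros_like(frame)
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def segment_somitoid(frame: np.ndarray, opening_radius: int = 2) -> Mask:
    """Segment the somitoid from a normalised 2D frame.

    Otsu threshold, binary opening (default radius 2 px), keep the largest
    connected component, fill holes.
    """
    frame = np.asarray(frame, dtype=float)
    thr = threshold_otsu(frame)
    fg = frame > thr
    if not fg.any():
        raise SegmentationEmptyError("segmentation-empty: no foreground above threshold")
    fg = opening(fg, disk(opening_radius))
    if not fg.any():
        raise SegmentationEmptyError("segmentation-empty: opening removed all foreground")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return Mask(data=fg, source="builtin")


def time_mean_frame(movie: Movie) -> np.ndarray:
    """Time-averaged 2D frame (movie must already be z-projected)."""
    if movie.has_z:
        raise ValueError("project the z dimension first")
    return movie.data.mean(axis=0)
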