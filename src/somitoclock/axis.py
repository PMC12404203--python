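"""Anteroposterior axis construction and somitoid morphometrics.

The midline of the (curved, elongated) somitoid is recovered from its binary
mask in four steps: principal axis of the foreground pixels, K-means
clustering of the pixel coordinates seeded along that axis, exact
travelling-salesman ordering of the cluster centres (an open path; exhaustive
enumeration, which is cheap at k=5), and piecewise-linear interpolation
resampled at 1-px arc-length steps.  The posterior end is then identified by
reporter intensity: the posterior presomitic mesoderm carries the higher
time-averaged signal, so s=0 is placed at the endpoint whose surrounding disc
is brighter in the time-averaged movie (overridable).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import Mask, Movie, time_mean_frame

MAX_TSP_POINTS = 10


@dataclass
class AxisPath:
    """Oriented piecewise-linear A-P midline.

    ``polyline`` is (n, 2) of (row, col) at ~1 px arc spacing, posterior
    first; ``arclength`` is the cumulative arc length (px); ``s`` the
    normalised arc coordinate with s=0 at the posterior end.
    """

    cluster_centers: np.ndarray
    polyline: np.ndarray
    arclength: np.ndarray
    orientation: str = "posterior_first"

    @property
    def s(self) -> np.ndarray:
        return self.arclength / self.arclength[-1]

    @property
    def length_arc(self) -> float:
        return float(self.arclength[-1])

    @property
    def length_euclidean(self) -> float:
        return float(np.linalg.norm(self.polyline[-1] - self.polyline[0]))

    def reversed(self) -> "AxisPath":
        rev = self.polyline[::-1].copy()
        seg = np.linalg.norm(np.diff(rev, axis=0), axis=1)
        return AxisPath(
            cluster_centers=self.cluster_centers[::-1].copy(),
            polyline=rev,
            arclength=np.concatenate([[0.0], np.cumsum(seg)]),
        )


@dataclass
class Morphometrics:
    """Somitoid size and shape summary (pixel units)."""

    length_euclidean: float
    length_arc: float
    width: float
    lw_ratio: float
    shape_class: Literal["elongated", "round"]


def principal_axis(mask: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and major-axis unit vector of the mask foreground.

    The axis is the leading eigenvector of the second central moment matrix
    of the foreground pixel coordinates. Near-isotropic masks (eigenvalue
    ratio < 1.05) get a warning; the returned axis is still deterministic.
    """
    coords = np.argwhere(mask.data).astype(float)
    if coords.size == 0:
        raise ValueError("empty mask")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] > 0 and evals[1] / evals[0] < 1.05:
        warnings.warn("mask is nearly isotropic: major axis is ill-defined",
                      stacklevel=2)
    vec = evecs[:, 1]
    # deterministic sign: positive row component, tie-break on col
    if vec[0] < 0 or (vec[0] == 0 and vec[1] < 0):
        vec = -vec
    return centroid, vec


def cluster_centers(
    mask: Mask,
    axis: tuple[np.ndarray, np.ndarray],
    k: int = 5,
) -> np.ndarray:
    """K-means centres of the foreground pixels, seeded along the major axis.

    Seeds are k points equally spaced along the part of the major-axis chord
    that lies inside the mask, which makes the clustering deterministic and
    spread along the tissue.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    coords = np.argwhere(mask.data).astype(float)
    if coords.shape[0] < k:
        raise ValueError("mask has fewer foreground pixels than clusters")
    centroid, vec = axis
    # project foreground onto the axis to find the in-mask chord extent
    proj = (coords - centroid) @ vec
    lo, hi = proj.min(), proj.max()
    offsets = np.linspace(lo, hi, k + 2)[1:-1]
    seeds = centroid + offsets[:, None] * vec
    km = KMeans(n_clusters=k, init=seeds, n_init=1, max_iter=100, tol=1e-6)
    km.fit(coords)
    return km.cluster_centers_


def order_clusters_tsp(centers: np.ndarray) -> np.ndarray:
    """Exact shortest open path through the cluster centres.

    All n!/2 distinct open orderings are enumerated (n <= 10); ties are
    broken by the lexicographically smallest index sequence.
    """
    centers = np.asarray(centers, dtype=float)
    n = centers.shape[0]
    if n < 2:
        raise ValueError("need at least 2 centers")
    if n > MAX_TSP_POINTS:
        raise ValueError(f"exhaustive TSP limited to {MAX_TSP_POINTS} points")
    dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    best_len = np.inf
    best: tuple[int, ...] | None = None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:  # each open path seen once
            continue
        length = sum(dist[perm[i], perm[i + 1]] for i in range(n - 1))
        if length < best_len - 1e-12:
            best_len = length
            best = perm
    assert best is not None
    return centers[list(best)]


def build_axis(
    ordered_centers: np.ndarray,
    mask: Mask,
    movie: Movie | None = None,
    orientation: Literal["auto", "keep", "reverse"] = "auto",
) -> AxisPath:
    """Piecewise-linear midline through the ordered centres, oriented P->A.

    The polyline is resampled at 1-px arc-length steps.  With
    ``orientation="auto"`` the posterior (s=0) end is the endpoint with the
    higher time-averaged reporter intensity in a disc of radius half the mean
    tissue width; "keep"/"reverse" override the rule.
    """
    centers = np.asarray(ordered_centers, dtype=float)
    # collapse duplicate consecutive centres
    keep = np.ones(len(centers), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(centers, axis=0), axis=1) > 1e-9
    if not keep.all():
        warnings.warn("duplicate consecutive centers collapsed", stacklevel=2)
        centers = centers[keep]
    if len(centers) < 2:
        raise ValueError("need at least 2 distinct centers")

    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n_samples = max(int(round(total)) + 1, 2)
    s_grid = np.linspace(0.0, total, n_samples)
    poly = np.column_stack([
        np.interp(s_grid, cum, centers[:, 0]),
        np.interp(s_grid, cum, centers[:, 1]),
    ])

    flip = False
    if orientation in ("auto", "reverse") and movie is not None:
        flip = not _posterior_is_first(poly, mask, movie)
        if orientation == "reverse":  # override: flip the auto assignment
            flip = not flip
    elif orientation == "reverse":
        flip = True

    if flip:
        poly = poly[::-1].copy()
        centers = centers[::-1].copy()
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return AxisPath(cluster_centers=centers, polyline=poly, arclength=arclength)


def _posterior_is_first(poly: np.ndarray, mask: Mask, movie: Movie) -> bool:
    """True if the first polyline endpoint is the brighter (posterior) one."""
    mean_frame = time_mean_frame(movie)
    arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
    mean_width = mask.data.sum() / max(arc, 1.0)
    radius = max(mean_width / 2.0, 3.0)
    h, w = mean_frame.shape
    rr, cc = np.mgrid[0:h, 0:w]

    def disc_mean(pt: np.ndarray) -> float:
        d2 = (rr - pt[0]) ** 2 + (cc - pt[1]) ** 2
        sel = d2 <= radius**2
        return float(mean_frame[sel].mean()) if sel.any() else -np.inf

    return disc_mean(poly[0]) >= disc_mean(poly[-1])


def perpendicular_chord(mask: Mask, point: np.ndarray, normal: np.ndarray,
                        max_half: float | None = None) -> float:
    """Length (px) of the in-mask chord through ``point`` along ``normal``."""
    h, w = mask.data.shape
    if max_half is None:
        max_half = float(np.hypot(h, w))
    offsets = np.arange(-max_half, max_half + 1.0)
    pts = point + offsets[:, None] * normal
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    inside = mask.data[rr, cc]
    # contiguous run containing the centre sample
    centre = len(offsets) // 2
    if not inside[centre]:
        return 0.0
    left = centre
    while left > 0 and inside[left - 1]:
        left -= 1
    right = centre
    while right < len(offsets) - 1 and inside[right + 1]:
        right += 1
    return float(right - left + 1)


def _local_normals(poly: np.ndarray) -> np.ndarray:
    """Unit normals to the polyline at every sample (central differences)."""
    tang = np.gradient(poly, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def measure_morphometrics(
    mask: Mask, axis: AxisPath, elongation_threshold: float = 1.5
) -> Morphometrics:
    """Length, width and shape class of the somitoid.

    Length is reported both as the Euclidean distance between the axis
    endpoints and as the midline arc length; width is the maximum
    perpendicular in-mask chord sampled along the axis. The length:width
    ratio (Euclidean length) against ``elongation_threshold`` assigns
    elongated vs round.
    """
    normals = _local_normals(axis.polyline)
    step = max(len(axis.polyline) // 100, 1)
    widths = [
        perpendicular_chord(mask, axis.polyline[i], normals[i])
        for i in range(0, len(axis.polyline), step)
    ]
    width = float(max(widths))
    le = axis.length_euclidean
    ratio = le / width if width > 0 else np.inf
    return Morphometrics(
        length_euclidean=le,
        length_arc=axis.length_arc,
        width=width,
        lw_ratio=ratio,
        shape_class="elongated" if ratio >= elongation_threshold else "round",
    )


def axis_from_mask(
    mask: Mask,
    movie: Movie | None = None,
    k: int = 5,
    orientation: Literal["auto", "keep", "reverse"] = "auto",
) -> AxisPath:
    """Convenience wrapper: principal axis -> K-means -> TSP -> AxisPath."""
    pa = principal_axis(mask)
    centers = cluster_centers(mask, pa, k=k)
    ordered = order_clusters_tsp(centers)
    return build_axis(ordered, mask, movie, orientation=orientation)
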