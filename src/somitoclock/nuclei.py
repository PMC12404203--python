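"""Per-nucleus marker quantification, bimodal classification, effect sizes.

Works downstream of nuclear segmentation: given an intensity image plus a
label mask (or a ready-made per-cell table), it measures mean ROI
intensities, drops cells whose centroids fall within 10% of the image
borders, derives a classification metric per marker (log total signal, or
mean absolute deviation for punctate markers), splits the bimodal metric
histogram at the deepest local minimum between its two dominant modes, and
quantifies group differences with the rank-based effect size
``r = |Z| / sqrt(N)`` (small < 0.3, moderate < 0.5, large >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats


@dataclass
class ClassificationResult:
    """Threshold classification of cells into negative/positive."""

    metric_name: str
    threshold: float
    labels: np.ndarray  # per-cell {"negative", "positive"}
    proportions: pd.DataFrame  # per group: negative/positive fractions


@dataclass
class EffectSize:
    """Rank-sum effect size between two groups."""

    W: float
    n1: int
    n2: int
    Z: float
    r: float
    magnitude: str

    @staticmethod
    def magnitude_band(r: float) -> str:
        if r < 0.3:
            return "small"
        if r < 0.5:
            return "moderate"
        return "large"


def roi_mean_intensities(image: np.ndarray, label_mask: np.ndarray) -> pd.DataFrame:
    """Per-label centroid, area and mean intensity.

    ``image`` may be 2D (one channel) or ``(c, y, x)``; channels become
    columns ``intensity`` / ``intensity_c{i}``.
    """
    label_mask = np.asarray(label_mask)
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("label mask contains no ROIs")
    image = np.asarray(image, dtype=float)
    channels = image[None] if image.ndim == 2 else image
    if channels.shape[-2:] != label_mask.shape:
        raise ValueError("image and label mask shapes differ")

    centroids = ndimage.center_of_mass(label_mask > 0, label_mask, labels)
    areas = ndimage.sum_labels(np.ones_like(label_mask), label_mask, labels)
    table = pd.DataFrame({
        "cell_id": labels,
        "row": [c[0] for c in centroids],
        "col": [c[1] for c in centroids],
        "area_px": areas.astype(int),
    })
    for ci, chan in enumerate(channels):
        name = "intensity" if channels.shape[0] == 1 else f"intensity_c{ci}"
        table[name] = ndimage.mean(chan, label_mask, labels)
    return table


def filter_boundary_cells(
    table: pd.DataFrame, image_shape: tuple[int, int], margin_frac: float = 0.10
) -> pd.DataFrame:
    """Drop cells whose centroid lies within ``margin_frac`` of any border."""
    if not 0 <= margin_frac < 0.5:
        raise ValueError("margin_frac must be in [0, 0.5)")
    h, w = image_shape
    mr, mc = margin_frac * h, margin_frac * w
    keep = (
        (table["row"] >= mr) & (table["row"] <= h - mr)
        & (table["col"] >= mc) & (table["col"] <= w - mc)
    )
    return table.loc[keep].reset_index(drop=True)


def marker_metric(
    table: pd.DataFrame,
    channel: str = "intensity",
    metric: str = "log_total",
    image: np.ndarray | None = None,
    label_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell classification metric.

    ``log_total``: natural log of (mean * area + 1), the total nuclear signal
    with a +1 offset.  ``mean_abs_dev``: mean absolute deviation of the
    per-pixel intensities inside each ROI (requires ``image`` and
    ``label_mask``), suited to punctate markers.
    """
    if channel not in table.columns:
        raise ValueError(f"channel column {channel!r} not in table")
    if metric == "log_total":
        total = table[channel].to_numpy(dtype=float) * table["area_px"].to_numpy()
        return np.log(total + 1.0)
    if metric == "mean_abs_dev":
        if image is None or label_mask is None:
            raise ValueError("mean_abs_dev needs the image and label mask")
        image = np.asarray(image, dtype=float)
        out = np.empty(len(table))
        for i, cid in enumerate(table["cell_id"].to_numpy()):
            px = image[label_mask == cid]
            out[i] = np.abs(px - px.mean()).mean() if px.size else np.nan
        return out
    raise ValueError(f"unknown metric {metric!r}")


def mean_abs_dev(values: np.ndarray) -> float:
    """Mean absolute deviation about the mean."""
    values = np.asarray(values, dtype=float)
    return float(np.abs(values - values.mean()).mean())


def bimodal_threshold(values: np.ndarray, smooth_bins: int = 3) -> float:
    """Histogram-valley threshold between two populations.

    Freedman-Diaconis binning, smoothed with a ``smooth_bins`` moving
    average; the threshold is the centre of the deepest local minimum
    strictly between the two highest local maxima.  Raises if no interior
    minimum exists ("not bimodal").
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise ValueError("need at least 50 values")
    edges = np.histogram_bin_edges(values, bins="fd")
    if edges.size < 4:
        raise ValueError("not bimodal: degenerate histogram")
    counts, edges = np.histogram(values, bins=edges)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts.astype(float), kernel, mode="same")

    maxima, _ = signal.find_peaks(smooth)
    if maxima.size < 2:
        raise ValueError("not bimodal: fewer than two histogram modes")
    top_two = maxima[np.argsort(smooth[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    interior = np.arange(lo + 1, hi)
    if interior.size == 0:
        raise ValueError("not bimodal: modes are adjacent")
    minima, _ = signal.find_peaks(-smooth[lo:hi + 1])
    minima = minima + lo
    if minima.size == 0:
        minima = interior
    valley = minima[np.argmin(smooth[minima])]
    return float(0.5 * (edges[valley] + edges[valley + 1]))


def classify_cells(
    values: np.ndarray,
    threshold: float,
    groups: np.ndarray | None = None,
    metric_name: str = "metric",
) -> ClassificationResult:
    """Label cells negative (metric < threshold) or positive (>=)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.where(values >= threshold, "positive", "negative")
    if groups is None:
        groups = np.full(values.size, "all")
    df = pd.DataFrame({"group": np.asarray(groups), "label": labels})
    props = (
        df.groupby("group")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["negative", "positive"], fill_value=0.0)
    )
    return ClassificationResult(
        metric_name=metric_name, threshold=float(threshold),
        labels=labels, proportions=props,
    )


def rank_effect_size(group_a: np.ndarray, group_b: np.ndarray) -> EffectSize:
    """Rank-based effect size from the Mann-Whitney statistic.

    ``W`` is the Mann-Whitney U of group A (midranks for ties);
    ``Z = |W - n1 n2 / 2| / sqrt(n1 n2 (n1 + n2 + 1) / 12)`` (no tie
    correction of the variance) and ``r = Z / sqrt(n1 + n2)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 8 or b.size < 8:
        raise ValueError("normal approximation needs n >= 8 per group")
    W = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    return effect_size_from_w(W, a.size, b.size)


def effect_size_from_w(W: float, n1: int, n2: int) -> EffectSize:
    """Effect size ``r = |Z|/sqrt(N)`` from a rank-sum statistic and sizes."""
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    Z = abs(W - mu) / sigma
    r = Z / np.sqrt(n1 + n2)
    return EffectSize(W=float(W), n1=int(n1), n2=int(n2), Z=float(Z),
                      r=float(r), magnitude=EffectSize.magnitude_band(float(r)))
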