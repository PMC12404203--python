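"""Kymograph construction and oscillation quantification.

A kymograph is built by averaging the filtered reporter signal along the
local perpendicular to the A-P axis at every midline sample, giving a 2D
array of axis position (posterior at row 0) by time.  Oscillation features
are read from the anterior region of the kymograph: peaks and troughs under a
minimum-period constraint, the period as the time between successive peaks
(averaged over at most the first three intervals), peak/trough intensity
levels, per-cycle amplitude, damping, and an ordinal 0-3 directionality score
for whether expression waves progress posterior-to-anterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, stats

from .axis import AxisPath, _local_normals
from .preprocess import Mask, Movie

DEFAULT_MIN_PERIOD_H = 3.0
DEFAULT_PROMINENCE_FRAC = 0.10
DEFAULT_OFFSET_FRAC = 0.8


@dataclass
class Kymograph:
    """Axis-position x time map of perpendicular-averaged signal."""

    data: np.ndarray  # (n_axis_samples, n_frames)
    s_step: float  # px between rows
    t_step: float  # minutes between columns

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Kymograph.data must be 2D")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class OscillationSummary:
    """Per-somitoid oscillation features (times in minutes, intensities a.u.)."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    periods: np.ndarray
    mean_period: float  # nan when < 2 peaks
    peak_intensity: float
    trough_intensity: float
    amplitude: float
    n_peaks: int
    damping_ratio: float
    directionality_score: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class CohortComparison:
    """Two-cohort comparison of one oscillation feature."""

    feature: str
    mean_a: float
    mean_b: float
    ratio_percent: float  # 100 * mean_b / mean_a
    difference: float  # mean_b - mean_a
    ci_low: float  # bootstrap 95% CI of the difference
    ci_high: float
    ratio_ci_low: float
    ratio_ci_high: float
    n_a: int = 0
    n_b: int = 0


def filter_movie(movie: Movie, median_size: int = 3, gaussian_sigma: float = 1.0) -> Movie:
    """Despeckle and smooth each frame: 3x3 median, then Gaussian sigma=1 px."""
    if movie.has_z:
        raise ValueError("project the z dimension before filtering")
    out = np.empty_like(movie.data, dtype=float)
    for i in range(movie.n_frames):
        frame = ndimage.median_filter(movie.data[i], size=median_size)
        out[i] = ndimage.gaussian_filter(frame, sigma=gaussian_sigma)
    return replace(movie, data=out)


def build_kymograph(
    movie: Movie,
    axis: AxisPath,
    mask: Mask,
    smooth_sigma: float = 1.0,
    max_half_width: float | None = None,
) -> Kymograph:
    """Average the movie along local perpendiculars to the axis.

    For every axis sample the signal is sampled at 1-px steps along the local
    normal, clipped to the mask, and averaged; the resulting 2D kymograph
    (posterior at row 0) is then Gaussian-smoothed with ``smooth_sigma``.
    Rows whose perpendicular leaves the mask entirely are filled from the
    nearest valid row with a warning.
    """
    if movie.has_z:
        raise ValueError("project the z dimension before building a kymograph")
    h, w = mask.data.shape
    if max_half_width is None:
        # generous bound: half the larger mask bounding-box side
        rows_any = np.flatnonzero(mask.data.any(axis=1))
        cols_any = np.flatnonzero(mask.data.any(axis=0))
        extent = max(rows_any[-1] - rows_any[0], cols_any[-1] - cols_any[0])
        max_half_width = extent / 2.0 + 2.0

    normals = _local_normals(axis.polyline)
    offsets = np.arange(-max_half_width, max_half_width + 1.0)
    # sample coordinates: (n_axis, n_off, 2)
    pts = axis.polyline[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rr = pts[..., 0]
    cc = pts[..., 1]
    in_bounds = (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
    ri = np.clip(np.round(rr).astype(int), 0, h - 1)
    ci = np.clip(np.round(cc).astype(int), 0, w - 1)
    valid = in_bounds & mask.data[ri, ci]

    n_axis = axis.polyline.shape[0]
    counts = valid.sum(axis=1)
    kymo = np.zeros((n_axis, movie.n_frames))
    flat_coords = np.stack([rr.ravel(), cc.ravel()])
    for t in range(movie.n_frames):
        sampled = ndimage.map_coordinates(
            movie.data[t], flat_coords, order=1, mode="nearest"
        ).reshape(n_axis, offsets.size)
        sums = np.where(valid, sampled, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            kymo[:, t] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} axis rows had no in-mask perpendicular samples; "
            "filled from nearest valid row", stacklevel=2)
        valid_rows = np.flatnonzero(~empty)
        for r in np.flatnonzero(empty):
            kymo[r] = kymo[valid_rows[np.argmin(np.abs(valid_rows - r))]]

    if smooth_sigma > 0:
        kymo = ndimage.gaussian_filter(kymo, sigma=smooth_sigma)
    s_step = axis.arclength[-1] / max(n_axis - 1, 1)
    return Kymograph(data=kymo, s_step=s_step, t_step=movie.frame_interval_min)


def extract_anterior_trace(
    kymo: Kymograph, offset_frac: float = DEFAULT_OFFSET_FRAC, window: int = 5
) -> np.ndarray:
    """Time series from the anterior region: mean of a ``window``-row band
    centred on the row nearest arc fraction ``offset_frac``."""
    if not 0 < offset_frac < 1:
        raise ValueError("offset_frac must be in (0, 1)")
    centre = int(round(offset_frac * (kymo.n_rows - 1)))
    half = window // 2
    lo, hi = centre - half, centre + half + 1
    if lo < 0 or hi > kymo.n_rows:
        warnings.warn("anterior window clipped to kymograph extent", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, kymo.n_rows)
    return kymo.data[lo:hi].mean(axis=0)


def detect_extrema(
    trace: np.ndarray,
    frame_interval_min: float,
    min_period_h: float = DEFAULT_MIN_PERIOD_H,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak and trough frame indices under a minimum-period constraint.

    Local maxima (and minima, via the negated trace) must be at least the
    minimum period apart and have prominence of at least ``prominence_frac``
    of the trace range.  Peaks and troughs are forced to interleave by
    dropping the weaker of two same-type neighbours.
    """
    trace = np.asarray(trace, dtype=float)
    min_frames = int(np.floor(min_period_h * 60.0 / frame_interval_min))
    if trace.size < 2 * min_frames:
        raise ValueError("trace shorter than two minimum periods")
    rng_ = float(trace.max() - trace.min())
    if rng_ == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    prom = prominence_frac * rng_
    peaks, _ = signal.find_peaks(trace, distance=max(min_frames, 1), prominence=prom)
    troughs, _ = signal.find_peaks(-trace, distance=max(min_frames, 1), prominence=prom)
    return _interleave(trace, peaks, troughs)


def _interleave(
    trace: np.ndarray, peaks: np.ndarray, troughs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the weaker of two same-type neighbours so extrema alternate."""
    events = sorted(
        [(int(i), "p") for i in peaks] + [(int(i), "t") for i in troughs])
    cleaned: list[tuple[int, str]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx = cleaned[-1][0]
            if kind == "p":
                keep_new = trace[idx] > trace[prev_idx]
            else:
                keep_new = trace[idx] < trace[prev_idx]
            if keep_new:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    p = np.array([i for i, k in cleaned if k == "p"], dtype=int)
    t = np.array([i for i, k in cleaned if k == "t"], dtype=int)
    return p, t


def summarize_oscillation(
    trace: np.ndarray,
    extrema: tuple[np.ndarray, np.ndarray],
    frame_interval_min: float,
    max_period_intervals: int | None = 3,
    directionality: int | None = None,
) -> OscillationSummary:
    """Reduce a trace plus detected extrema to oscillation features.

    The mean period uses at most the first ``max_period_intervals`` inter-peak
    intervals (pass ``None`` for the full series); per-cycle amplitude is the
    peak minus the mean of its flanking troughs.
    """
    trace = np.asarray(trace, dtype=float)
    peaks, troughs = extrema
    peak_times = peaks * frame_interval_min
    trough_times = troughs * frame_interval_min
    periods = np.diff(peak_times)
    if periods.size:
        use = periods if max_period_intervals is None else periods[:max_period_intervals]
        mean_period = float(np.mean(use))
    else:
        mean_period = float("nan")

    peak_i = float(trace[peaks].mean()) if peaks.size else float("nan")
    trough_i = float(trace[troughs].mean()) if troughs.size else float("nan")

    amps = []
    for p in peaks:
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        if before.size and after.size:
            amps.append(trace[p] - 0.5 * (trace[before[-1]] + trace[after[0]]))
    if not amps and peaks.size and troughs.size:
        amps = [peak_i - trough_i]
    amplitude = float(np.mean(amps)) if amps else float("nan")
    damping = float(amps[-1] / amps[0]) if len(amps) >= 2 and amps[0] != 0 else float("nan")

    return OscillationSummary(
        peak_times=peak_times,
        trough_times=trough_times,
        periods=periods,
        mean_period=mean_period,
        peak_intensity=peak_i,
        trough_intensity=trough_i,
        amplitude=amplitude,
        n_peaks=int(peaks.size),
        damping_ratio=damping,
        directionality_score=directionality,
    )


def directionality_score(
    kymo: Kymograph,
    offset_frac: float = DEFAULT_OFFSET_FRAC,
    min_period_h: float = DEFAULT_MIN_PERIOD_H,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    alpha: float = 0.05,
    oscillation_floor_frac: float = 0.05,
) -> int:
    """Ordinal 0-3 grading of posterior-to-anterior wave progression.

    Automated surrogate for manual scoring. The anterior trace defines the
    cycles: score 0 ("no/poor oscillations") if it has fewer than two
    detected peaks, or if its peak-to-trough span is below
    ``oscillation_floor_frac`` of the mean trace level (prominence alone is
    scale-free, so a flat noisy trace would otherwise pass). For each cycle
    the wave ridge is tracked across rows starting from the posterior row's
    peak — each row's peak is matched to the one nearest the previous row's
    matched time, which follows the travelling wave without phase wrapping —
    and the matched peak time is regressed against row index. A cycle counts
    as directional when the slope is positive with p < ``alpha``. Score 3 if
    >= 75% of cycles are directional, 2 if >= 50%, else 1.
    """
    trace = extract_anterior_trace(kymo, offset_frac)
    try:
        peaks, _ = detect_extrema(trace, kymo.t_step, min_period_h, prominence_frac)
    except ValueError:
        return 0
    if peaks.size < 2:
        return 0
    span = float(np.ptp(trace))
    if trace.mean() > 0 and span < oscillation_floor_frac * float(trace.mean()):
        return 0

    period_frames = float(np.median(np.diff(peaks)))
    # per-row peak detection under the same constraints
    row_peaks: list[np.ndarray] = []
    for r in range(kymo.n_rows):
        try:
            p, _ = detect_extrema(kymo.data[r], kymo.t_step, min_period_h,
                                  prominence_frac)
        except ValueError:
            p = np.array([], dtype=int)
        row_peaks.append(p)

    post_peaks = row_peaks[0]
    n_cycles = 0
    n_directional = 0
    for anchor in post_peaks:
        rows_used: list[int] = []
        times: list[float] = []
        current = float(anchor)
        for r in range(kymo.n_rows):
            cand = row_peaks[r]
            if cand.size == 0:
                continue
            j = int(np.argmin(np.abs(cand - current)))
            if abs(cand[j] - current) > period_frames / 2.0:
                continue
            current = float(cand[j])
            rows_used.append(r)
            times.append(current * kymo.t_step)
        if len(rows_used) < max(kymo.n_rows // 4, 5):
            continue
        n_cycles += 1
        res = stats.linregress(rows_used, times)
        if res.slope > 0 and res.pvalue < alpha:
            n_directional += 1

    if n_cycles == 0:
        return 1
    frac = n_directional / n_cycles
    if frac >= 0.75:
        return 3
    if frac >= 0.50:
        return 2
    return 1


def compare_cohorts(
    summaries_a: list[OscillationSummary],
    summaries_b: list[OscillationSummary],
    feature: str,
    seed: int = 0,
    n_boot: int = 2000,
) -> CohortComparison:
    """Compare one oscillation feature between two cohorts.

    Reports group means, the b/a ratio in percent, the difference, and seeded
    bootstrap 95% percentile CIs (``n_boot`` resamples) for both.
    """
    if not summaries_a or not summaries_b:
        raise ValueError("both cohorts must be non-empty")
    a = np.array([getattr(s, feature) for s in summaries_a], dtype=float)
    b = np.array([getattr(s, feature) for s in summaries_b], dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"no finite values for feature {feature!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boot_a = a[idx_a].mean(axis=1)
    boot_b = b[idx_b].mean(axis=1)
    diff = boot_b - boot_a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * boot_b / boot_a
    return CohortComparison(
        feature=feature,
        mean_a=mean_a,
        mean_b=mean_b,
        ratio_percent=100.0 * mean_b / mean_a,
        difference=mean_b - mean_a,
        ci_low=float(np.percentile(diff, 2.5)),
        ci_high=float(np.percentile(diff, 97.5)),
        ratio_ci_low=float(np.percentile(ratio, 2.5)),
        ratio_ci_high=float(np.percentile(ratio, 97.5)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
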