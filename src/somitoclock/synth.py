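"""Synthetic somitoid movies, protein-decay series, and nuclear marker tables.

The movie generator emulates what the oscillation pipeline sees in real
recordings: an elongated, gently bent somitoid whose reporter intensity
oscillates with a stated period, either as a travelling wave launched at the
posterior end or as a wave originating at the centre of the tissue.  Inside
the tissue band the noiseless intensity at arc-fraction ``s`` and time ``t``
(minutes) is::

    I(s, t) = B + A * D(t) * (1 + cos(2*pi*t/T - phi(s))) / 2

with trough level ``B`` (baseline), amplitude ``A``, optional exponential
damping ``D(t) = exp(-t / damping_tau_min)`` and phase
``phi(s) = 2*pi*s / wavelength_frac`` for a posterior origin or
``phi(s) = 2*pi*|s - 0.5| / wavelength_frac`` for a centre origin.  Additive
Gaussian camera noise is applied everywhere; pixels outside the band sit at
5% of the baseline.  The band tapers toward the anterior (real somitoids are
widest at the posterior), which is what lets the intensity-based
posterior-identification rule of the axis module work on these movies.

Named presets carry the study conditions as designed ground truth: a 258-min
(4.3 h) posterior-origin wild-type clock versus a 278-min centre-origin
mutant whose trough sits at 188% of wild type and whose amplitude is 51% of
wild type, so that pipeline-recovery checks have known answers.

Decay series follow ``y(t) = (1 - b) * exp(-k t) + b`` with multiplicative
lognormal densitometry noise; nuclear tables draw log-intensities from a
two-component Gaussian mixture with recorded true labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .preprocess import Movie

BACKGROUND_FRAC = 0.05  # background outside the mask, as a fraction of baseline
ANTERIOR_TAPER = 0.35  # fractional width loss from posterior to anterior end


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {msg}")


@dataclass(frozen=True)
class WavePreset:
    """Parameters of one synthetic oscillating-somitoid movie."""

    name: str
    period_min: float
    origin: Literal["posterior", "center"]
    baseline: float
    amplitude: float
    damping_tau_min: float = math.inf
    noise_sd: float = 8.0
    wavelength_frac: float = 1.0
    band_length_px: int = 180
    band_width_px: int = 60
    curvature: float = 0.12
    frame_interval_min: float = 10.0
    duration_min: float = 1560.0
    image_shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.period_min > 0, "period_min", "must be > 0")
        _require(self.amplitude >= 0, "amplitude", "must be >= 0")
        _require(self.baseline >= 0, "baseline", "must be >= 0")
        _require(0 < self.wavelength_frac <= 2, "wavelength_frac", "must be in (0, 2]")
        _require(
            self.duration_min >= 2 * self.period_min,
            "duration_min",
            "must cover at least two periods",
        )
        _require(self.frame_interval_min > 0, "frame_interval_min", "must be > 0")
        _require(self.origin in ("posterior", "center"), "origin", "posterior|center")
        _require(self.damping_tau_min > 0, "damping_tau_min", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows about a movie, for recovery checks."""

    mask: np.ndarray
    axis_polyline: np.ndarray  # (n, 2) rows of (row, col), posterior first
    true_period_min: float
    true_trough: float
    true_peak: float
    true_amplitude: float
    origin: str

    @property
    def posterior_point(self) -> np.ndarray:
        return self.axis_polyline[0]

    @property
    def anterior_point(self) -> np.ndarray:
        return self.axis_polyline[-1]


@dataclass(frozen=True)
class DecaySimSpec:
    """Parameters of a simulated replicate protein-decay time course."""

    k: float = 0.49
    b: float = 0.14
    timepoints_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    n_replicates: int = 3
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.k > 0, "k", "must be > 0")
        _require(0 <= self.b < 1, "b", "must be in [0, 1)")
        _require(len(self.timepoints_h) > 0, "timepoints_h", "must be non-empty")
        _require(0.0 in self.timepoints_h, "timepoints_h", "must include t=0")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")


@dataclass(frozen=True)
class NucleiSimSpec:
    """Parameters of a simulated bimodal per-nucleus marker table."""

    n_cells: int = 2000
    neg_mean: float = 4.0
    neg_sd: float = 0.5
    pos_mean: float = 6.5
    pos_sd: float = 0.5
    pos_fraction: float = 0.5
    image_shape: tuple[int, int] = (1024, 1024)
    margin_placement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(self.pos_mean > self.neg_mean, "pos_mean", "must exceed neg_mean")
        _require(0 <= self.pos_fraction <= 1, "pos_fraction", "must be in [0, 1]")
        _require(self.neg_sd > 0 and self.pos_sd > 0, "neg_sd/pos_sd", "must be > 0")


# Designed ground truth for pipeline-recovery checks: a 4.3 h posterior-origin
# wild-type clock vs a centre-origin mutant with +20 min period (embedded),
# trough at 188% and amplitude at 51% of wild type; pre-embedding cohorts carry
# the milder (+6 min, 138%, 95%) differences over an 18 h recording.
PRESETS: dict[str, WavePreset] = {
    "wt_embedded": WavePreset(
        name="wt_embedded", period_min=258.0, origin="posterior",
        baseline=100.0, amplitude=200.0, duration_min=1560.0,
    ),
    "s2513a_embedded": WavePreset(
        name="s2513a_embedded", period_min=278.0, origin="center",
        baseline=188.0, amplitude=102.0, duration_min=1560.0,
    ),
    "s2513a_embedded_damped": WavePreset(
        name="s2513a_embedded_damped", period_min=278.0, origin="center",
        baseline=188.0, amplitude=102.0, damping_tau_min=300.0,
        duration_min=1560.0,
    ),
    "wt_preembed": WavePreset(
        name="wt_preembed", period_min=258.0, origin="posterior",
        baseline=100.0, amplitude=200.0, duration_min=1080.0,
    ),
    "s2513a_preembed": WavePreset(
        name="s2513a_preembed", period_min=264.0, origin="center",
        baseline=138.0, amplitude=190.0, duration_min=1080.0,
    ),
}


def _band_geometry(preset: WavePreset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bent, tapered band: returns (mask, s_map, midline polyline).

    The midline is a quadratic bend whose arc length equals
    ``band_length_px``; ``s_map[r, c]`` is the arc fraction of the nearest
    midline point for every pixel (NaN outside the band).
    """
    h, w = preset.image_shape
    n_dense = 4 * preset.band_length_px
    u = np.linspace(-0.5, 0.5, n_dense)

    def polyline(chord: float) -> np.ndarray:
        cols = w / 2 + u * chord
        rows = h / 2 + preset.curvature * preset.band_length_px * (2 * u) ** 2
        return np.column_stack([rows, cols])

    # one secant-style correction so midline arc length ~= band_length_px
    pts = polyline(float(preset.band_length_px))
    arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    pts = polyline(preset.band_length_px**2 / arc)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_dense = cum / cum[-1]

    tree = cKDTree(pts)
    rr, cc = np.mgrid[0:h, 0:w]
    dist, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]), workers=-1)
    s_pix = s_dense[idx]
    half_width = 0.5 * preset.band_width_px * (1.0 - ANTERIOR_TAPER * s_pix)
    inside = dist <= half_width
    mask = inside.reshape(h, w)
    s_map = np.where(mask, s_pix.reshape(h, w), np.nan)
    return mask, s_map, pts


def generate_somitoid_movie(preset: WavePreset) -> tuple[Movie, GroundTruth]:
    """Render one movie and its ground truth from a :class:`WavePreset`."""
    mask, s_map, midline = _band_geometry(preset)
    times = np.arange(0.0, preset.duration_min + 0.5 * preset.frame_interval_min,
                      preset.frame_interval_min)
    rng = np.random.default_rng(preset.seed)

    s_in = s_map[mask]
    if preset.origin == "posterior":
        phi = 2 * np.pi * s_in / preset.wavelength_frac
    else:
        phi = 2 * np.pi * np.abs(s_in - 0.5) / preset.wavelength_frac

    omega = 2 * np.pi / preset.period_min
    damping = (np.exp(-times / preset.damping_tau_min)
               if np.isfinite(preset.damping_tau_min) else np.ones_like(times))

    h, w = preset.image_shape
    data = np.empty((times.size, h, w), dtype=np.float64)
    bg = BACKGROUND_FRAC * preset.baseline
    for i, (t, d) in enumerate(zip(times, damping)):
        frame = np.full((h, w), bg)
        frame[mask] = preset.baseline + preset.amplitude * d * (
            1.0 + np.cos(omega * t - phi)) / 2.0
        data[i] = frame
    if preset.noise_sd > 0:
        data += rng.normal(0.0, preset.noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)

    movie = Movie(
        data=data,
        frame_interval_min=preset.frame_interval_min,
        channel="reporter",
        meta={"preset": preset.name, "seed": preset.seed},
    )
    truth = GroundTruth(
        mask=mask,
        axis_polyline=midline,
        true_period_min=preset.period_min,
        true_trough=preset.baseline,
        true_peak=preset.baseline + preset.amplitude,
        true_amplitude=preset.amplitude,
        origin=preset.origin,
    )
    return movie, truth


def generate_cohort(
    preset: WavePreset, n: int, base_seed: int
) -> list[tuple[Movie, GroundTruth]]:
    """``n`` movies from one preset with seeds ``base_seed .. base_seed+n-1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_somitoid_movie(replace(preset, seed=base_seed + i))
            for i in range(n)]


def decay_model(t: np.ndarray, k: float, b: float) -> np.ndarray:
    """Exponential decay toward a background plateau: ``(1-b) exp(-k t) + b``."""
    return (1.0 - b) * np.exp(-k * np.asarray(t, dtype=float)) + b


def generate_decay_series(spec: DecaySimSpec, condition: str = "sim") -> pd.DataFrame:
    """Replicate decay time courses as a tidy table.

    Columns: condition, replicate, time_h, intensity.  Noise is
    multiplicative lognormal (densitometry error character); the t=0 value is
    NOT renormalised — normalisation is a pipeline step.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(sorted(spec.timepoints_h), dtype=float)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        y = decay_model(t, spec.k, spec.b)
        if spec.noise_cv > 0:
            y = y * np.exp(rng.normal(0.0, spec.noise_cv, size=t.size))
        rows.append(pd.DataFrame({
            "condition": condition, "replicate": rep, "time_h": t, "intensity": y,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_nuclei_table(spec: NucleiSimSpec, group: str = "sim") -> pd.DataFrame:
    """Per-cell marker table drawn from a two-component lognormal mixture.

    Columns: cell_id, row, col, area_px, intensity (per-cell mean, linear
    scale), group, true_label.  Centroids are uniform over the image
    (including the boundary margin when ``margin_placement``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    if spec.margin_placement:
        rows = rng.uniform(0, h, size=spec.n_cells)
        cols = rng.uniform(0, w, size=spec.n_cells)
    else:
        rows = rng.uniform(0.1 * h, 0.9 * h, size=spec.n_cells)
        cols = rng.uniform(0.1 * w, 0.9 * w, size=spec.n_cells)
    positive = rng.random(spec.n_cells) < spec.pos_fraction
    log_i = np.where(
        positive,
        rng.normal(spec.pos_mean, spec.pos_sd, size=spec.n_cells),
        rng.normal(spec.neg_mean, spec.neg_sd, size=spec.n_cells),
    )
    area = rng.integers(60, 140, size=spec.n_cells)
    return pd.DataFrame({
        "cell_id": np.arange(spec.n_cells),
        "row": rows,
        "col": cols,
        "area_px": area,
        "intensity": np.exp(log_i),
        "group": group,
        "true_label": np.where(positive, "positive", "negative"),
    })
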