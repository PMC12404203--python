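"""End-to-end pipelines tying the stages together, driven by a validated
configuration.

Three pipelines mirror the three analysis tracks: oscillation (movie ->
mask -> axis -> kymograph -> features), decay (normalise -> fit ->
half-life -> optional condition comparison), and nuclei (table -> boundary
filter -> metric -> threshold -> classification -> effect sizes).  Every run
is deterministic given the config and seeds, and reports embed the resolved
parameter set for auditability.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .axis import axis_from_mask, measure_morphometrics
from .decay import compare_conditions, fit_decay, normalize_to_t0
from .kymo import (
    OscillationSummary,
    build_kymograph,
    compare_cohorts,
    detect_extrema,
    directionality_score,
    extract_anterior_trace,
    filter_movie,
    summarize_oscillation,
)
from .preprocess import (
    Mask,
    Movie,
    normalize_plane,
    project_stack,
    segment_somitoid,
    time_mean_frame,
)
from .synth import PRESETS, DecaySimSpec, NucleiSimSpec, generate_cohort

logger = logging.getLogger("somitoclock")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their validated defaults."""

    projection_mode: str = "max"  # reporter projection statistic
    offset_frac: float = 0.8  # anterior window position along the axis
    k_clusters: int = 5
    elongation_threshold: float = 1.5
    min_period_h: float = 3.0
    prominence_frac: float = 0.10
    margin_frac: float = 0.10
    median_size: int = 3
    gaussian_sigma: float = 1.0
    kymo_sigma: float = 1.0
    orientation: str = "auto"  # posterior identification: auto|keep|reverse
    seed: int = 0
    n_bootstrap: int = 2000

    def __post_init__(self) -> None:
        checks = [
            (self.projection_mode in ("max", "mean"), "projection_mode must be max|mean"),
            (0 < self.offset_frac < 1, "offset_frac must be in (0, 1)"),
            (self.k_clusters >= 2, "k_clusters must be >= 2"),
            (self.k_clusters <= 10, "k_clusters must be <= 10 (exhaustive TSP)"),
            (self.elongation_threshold > 0, "elongation_threshold must be > 0"),
            (self.min_period_h > 0, "min_period_h must be > 0"),
            (0 < self.prominence_frac < 1, "prominence_frac must be in (0, 1)"),
            (0 <= self.margin_frac < 0.5, "margin_frac must be in [0, 0.5)"),
            (self.median_size >= 1, "median_size must be >= 1"),
            (self.gaussian_sigma >= 0, "gaussian_sigma must be >= 0"),
            (self.kymo_sigma >= 0, "kymo_sigma must be >= 0"),
            (self.orientation in ("auto", "keep", "reverse"),
             "orientation must be auto|keep|reverse"),
            (self.n_bootstrap >= 1, "n_bootstrap must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analyze_movie(
    movie: Movie,
    config: PipelineConfig | None = None,
    mask: Mask | None = None,
) -> tuple[OscillationSummary, dict]:
    """Run the full oscillation analysis on one movie.

    Returns the :class:`OscillationSummary` (with directionality score) and a
    dict of intermediates (mask, axis, kymograph, trace, morphometrics).
    An externally supplied ``mask`` overrides the builtin segmenter.
    """
    cfg = config or PipelineConfig()
    movie2d = project_stack(movie, mode=cfg.projection_mode)
    if mask is None:
        mask = segment_somitoid(normalize_plane(time_mean_frame(movie2d)))
    filtered = filter_movie(movie2d, cfg.median_size, cfg.gaussian_sigma)
    axis = axis_from_mask(mask, filtered, k=cfg.k_clusters,
                          orientation=cfg.orientation)
    kymo = build_kymograph(filtered, axis, mask, smooth_sigma=cfg.kymo_sigma)
    trace = extract_anterior_trace(kymo, cfg.offset_frac)
    extrema = detect_extrema(trace, movie2d.frame_interval_min,
                             cfg.min_period_h, cfg.prominence_frac)
    score = directionality_score(kymo, cfg.offset_frac, cfg.min_period_h,
                                 cfg.prominence_frac)
    summary = summarize_oscillation(trace, extrema, movie2d.frame_interval_min,
                                    directionality=score)
    morpho = measure_morphometrics(mask, axis, cfg.elongation_threshold)
    intermediates = {"mask": mask, "axis": axis, "kymograph": kymo,
                     "trace": trace, "morphometrics": morpho}
    return summary, intermediates


def run_oscillation_pipeline(
    movies: list[tuple[str, Movie]],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    masks: dict[str, Mask] | None = None,
) -> pd.DataFrame:
    """Analyse a batch of movies, writing every intermediate to ``out_dir``.

    Per-movie failures are logged and skipped; raises only if all movies
    fail. Returns the summary table (also written as CSV).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    min_frames = int(np.floor(cfg.min_period_h * 60))
    logger.info("oscillation pipeline: %d movies, config=%s", len(movies), cfg.to_dict())

    summaries, names = [], []
    for name, movie in movies:
        logger.info("movie %s: peak min-distance %d frames", name,
                    int(np.floor(min_frames / movie.frame_interval_min)))
        try:
            mask = masks.get(name) if masks else None
            summary, inter = analyze_movie(movie, cfg, mask=mask)
        except Exception:  # noqa: BLE001 - per-movie isolation
            logger.exception("movie %s failed; skipping", name)
            continue
        io.write_mask(out / f"{name}_mask.tif", inter["mask"])
        io.write_axis(out / f"{name}_axis.csv", inter["axis"])
        io.write_kymograph(out / f"{name}_kymo.tif", out / f"{name}_kymo.csv",
                           inter["kymograph"])
        summaries.append(summary)
        names.append(name)
    if not summaries:
        raise RuntimeError("all movies failed")
    table = io.summaries_to_frame(summaries, names)
    table.to_csv(out / "oscillation_summaries.csv", index=False)
    io.write_json(out / "resolved_config.json", cfg.to_dict())
    return table


def run_cohort_comparison(
    summaries_a, summaries_b, features: list[str],
    config: PipelineConfig | None = None,
) -> dict:
    """Compare named features between two cohorts of summaries."""
    cfg = config or PipelineConfig()
    out = {}
    for feat in features:
        c = compare_cohorts(summaries_a, summaries_b, feat,
                            seed=cfg.seed, n_boot=cfg.n_bootstrap)
        out[feat] = dataclasses.asdict(c)
    return out


def run_decay_pipeline(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    compare: bool = True,
) -> dict:
    """Fit the decay model per condition; optionally compare two conditions.

    Returns ``{"fits": {condition: fit dict}, "comparison": table or None}``;
    half-lives are additionally reported rounded to one decimal, matching how
    such fits are usually quoted.
    """
    normalized = normalize_to_t0(table)
    fits: dict[str, dict] = {}
    by_cond: dict[str, pd.DataFrame] = {}
    for cond, grp in normalized.groupby("condition"):
        by_cond[str(cond)] = grp
        try:
            fit = fit_decay(grp)
            d = dataclasses.asdict(fit)
            d["t_half_1dp"] = round(fit.t_half, 1) if np.isfinite(fit.t_half) else None
            fits[str(cond)] = d
        except Exception as exc:  # noqa: BLE001 - per-condition isolation
            logger.warning("condition %s unfittable: %s", cond, exc)
            fits[str(cond)] = {"converged": False, "error": str(exc)}

    comparison = None
    conds = sorted(by_cond)
    if compare and len(conds) == 2:
        comparison = compare_conditions(by_cond[conds[0]], by_cond[conds[1]])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cond, fit in fits.items():
            io.write_json(out / f"decay_fit_{cond}.json", fit)
        if comparison is not None:
            comparison.to_csv(out / "decay_comparison.csv", index=False)
    return {"fits": fits, "comparison": comparison}


def simulate_fixture_bundle(
    out_dir: str | Path,
    preset: str = "wt_embedded",
    n: int = 1,
    seed: int = 0,
) -> list[str]:
    """Write ``n`` synthetic movies + ground truths to ``out_dir``.

    Returns the manifest (relative file names, sorted).
    """
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for i, (movie, truth) in enumerate(generate_cohort(PRESETS[preset], n, seed)):
        stem = f"{preset}_{seed + i:04d}"
        io.write_movie(out / f"{stem}.tif", movie)
        io.write_mask(out / f"{stem}_truth_mask.tif", Mask(truth.mask))
        io.write_json(out / f"{stem}_truth.json", {
            "true_period_min": truth.true_period_min,
            "true_trough": truth.true_trough,
            "true_peak": truth.true_peak,
            "true_amplitude": truth.true_amplitude,
            "origin": truth.origin,
            "posterior_point": truth.posterior_point,
        })
        manifest += [f"{stem}.tif", f"{stem}.tif.json",
                     f"{stem}_truth_mask.tif", f"{stem}_truth.json"]
    return sorted(manifest)


def simulate_decay_csv(out_path: str | Path, k: float, b: float,
                       noise_cv: float, n_replicates: int, seed: int,
                       condition: str = "sim") -> pd.DataFrame:
    from .synth import generate_decay_series

    spec = DecaySimSpec(k=k, b=b, noise_cv=noise_cv,
                        n_replicates=n_replicates, seed=seed)
    table = generate_decay_series(spec, condition=condition)
    table.to_csv(out_path, index=False)
    return table


def simulate_nuclei_csv(out_path: str | Path, n_cells: int, pos_fraction: float,
                        seed: int, group: str = "sim") -> pd.DataFrame:
    from .synth import generate_nuclei_table

    spec = NucleiSimSpec(n_cells=n_cells, pos_fraction=pos_fraction, seed=seed)
    table = generate_nuclei_table(spec, group=group)
    table.to_csv(out_path, index=False)
    return table
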