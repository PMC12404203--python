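"""File I/O: multi-page TIFF movies with JSON metadata sidecars, mask TIFFs,
axis/summary CSVs and report JSONs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .axis import AxisPath
from .kymo import Kymograph, OscillationSummary
from .preprocess import Mask, Movie


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a multi-page 16-bit TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "frame_interval_min": movie.frame_interval_min,
        "pixel_size": movie.pixel_size,
        "channel": movie.channel,
        **movie.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> Movie:
    """Read a movie TIFF; metadata comes from the sidecar when present."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    return Movie(
        data=np.asarray(data, dtype=float),
        frame_interval_min=float(meta.pop("frame_interval_min", 10.0)),
        pixel_size=float(meta.pop("pixel_size", 1.0)),
        channel=meta.pop("channel", "reporter"),
        meta=meta,
    )


def write_mask(path: str | Path, mask: Mask) -> None:
    tifffile.imwrite(Path(path), (mask.data.astype(np.uint8)) * 255)


def read_mask(path: str | Path) -> Mask:
    data = tifffile.imread(Path(path))
    return Mask(data=np.asarray(data) > 0, source="external")


def write_axis(path: str | Path, axis: AxisPath) -> None:
    pd.DataFrame({
        "sample_index": np.arange(len(axis.polyline)),
        "row": axis.polyline[:, 0],
        "col": axis.polyline[:, 1],
        "arclength_px": axis.arclength,
        "s": axis.s,
    }).to_csv(path, index=False)


def write_kymograph(path_tiff: str | Path, path_csv: str | Path, kymo: Kymograph) -> None:
    tifffile.imwrite(Path(path_tiff), kymo.data.astype(np.float32))
    pd.DataFrame(kymo.data).to_csv(path_csv, index=False)


def summaries_to_frame(summaries: list[OscillationSummary],
                       names: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(summaries):
        rows.append({
            "somitoid": names[i] if names else f"somitoid_{i}",
            "mean_period_min": s.mean_period,
            "n_peaks": s.n_peaks,
            "peak_intensity": s.peak_intensity,
            "trough_intensity": s.trough_intensity,
            "amplitude": s.amplitude,
            "damping_ratio": s.damping_ratio,
            "directionality_score": s.directionality_score,
            "peak_times_min": ";".join(f"{t:g}" for t in s.peak_times),
            "trough_times_min": ";".join(f"{t:g}" for t in s.trough_times),
        })
    return pd.DataFrame(rows)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
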