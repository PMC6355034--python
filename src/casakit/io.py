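"""File formats: frame stacks, trajectory CSV, report writers.

Frame stacks travel as multi-page TIFF (lossless, no codec needed); AVI is
read and written through imageio when a video backend is installed and a
clear error names the file otherwise.  Trajectories use a flat CSV with
columns ``track_id, frame, x_px, y_px[, responsive]`` shared by the
simulator and the tracker, so downstream analyses are byte-identical
regardless of where tracks came from.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinematics import KinematicsResult, summarize
from .tracks import Trajectory, TrackSet

__all__ = [
    "read_video",
    "write_video",
    "read_tracks",
    "write_tracks",
    "write_kinematics",
    "write_json",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _to_gray_u8(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4:  # (T, H, W, C) -> luminance
        frames = (
            frames[..., 0] * 0.2126 + frames[..., 1] * 0.7152 + frames[..., 2] * 0.0722
        )
    if frames.dtype != np.uint8:
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    return frames


def read_video(path, fps: float | None = None) -> tuple[np.ndarray, float | None]:
    """Read a frame stack as 8-bit grayscale ``(T, H, W)`` plus its frame rate.

    TIFF stacks are read with tifffile; other containers (AVI, ...) go
    through imageio and require a video backend.  ``fps`` overrides any
    container metadata; TIFF carries none, so the returned rate is the
    override or None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return _to_gray_u8(frames), fps
    try:
        import imageio.v3 as iio

        frames = np.stack(list(iio.imiter(path)))
        meta = iio.immeta(path)
        container_fps = meta.get("fps")
    except Exception as exc:
        raise OSError(
            f"cannot read {path}: no video backend for this container "
            f"(install an imageio ffmpeg backend, or use a .tif stack): {exc}"
        ) from exc
    if frames.size == 0:
        raise OSError(f"empty video container: {path}")
    return _to_gray_u8(frames), fps if fps is not None else container_fps


def write_video(frames: np.ndarray, path, fps: float = 60.0) -> None:
    """Write a grayscale frame stack; TIFF natively, AVI via imageio if possible."""
    path = Path(path)
    frames = _to_gray_u8(frames)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, frames)
        return
    try:
        import imageio.v3 as iio

        iio.imwrite(path, frames, fps=fps)
    except Exception as exc:
        raise OSError(
            f"cannot write {path}: no video backend for this container "
            f"(use a .tif stack instead): {exc}"
        ) from exc


_REQUIRED_COLUMNS = ["track_id", "frame", "x_px", "y_px"]


def write_tracks(tracks: TrackSet, path) -> None:
    """Write a TrackSet to CSV; an empty set produces a header-only file."""
    rows = []
    has_resp = any(t.responsive is not None for t in tracks)
    for t in tracks:
        for (x, y), f in zip(t.points, t.frames):
            row = {"track_id": t.track_id, "frame": int(f), "x_px": x, "y_px": y}
            if has_resp:
                row["responsive"] = bool(t.responsive)
            rows.append(row)
    cols = _REQUIRED_COLUMNS + (["responsive"] if has_resp else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_tracks(path) -> TrackSet:
    """Read a trajectory CSV back into a TrackSet.

    Rows out of frame order are sorted per track with a warning; missing
    required columns raise a schema error listing them.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    trajectories = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy()
        if not np.all(np.diff(frames) > 0):
            warnings.warn(f"{path}: track {tid} rows out of frame order; sorting")
            grp = grp.sort_values("frame")
        responsive = bool(grp["responsive"].iloc[0]) if "responsive" in df.columns else None
        trajectories.append(
            Trajectory(
                track_id=int(tid),
                points=grp[["x_px", "y_px"]].to_numpy(dtype=float),
                frames=grp["frame"].to_numpy(dtype=int),
                responsive=responsive,
            )
        )
    return TrackSet(trajectories, meta={"source": str(path)})


def write_kinematics(results: list[KinematicsResult], path) -> None:
    """Per-track kinematics CSV plus a POPULATION summary row."""
    cols = [
        "track_id", "n_points", "vsl", "vcl", "vap", "lin", "wob", "str",
        "alh_mean", "alh_max", "bcf", "dnc", "mad", "fd", "motile", "progressive",
    ]
    rows = []
    for r in results:
        rows.append({
            "track_id": r.track_id, "n_points": r.n_points, "vsl": r.vsl,
            "vcl": r.vcl, "vap": r.vap, "lin": r.lin, "wob": r.wob,
            "str": r.str_, "alh_mean": r.alh_mean, "alh_max": r.alh_max,
            "bcf": r.bcf, "dnc": r.dnc, "mad": r.mad, "fd": r.fd,
            "motile": r.motile, "progressive": r.progressive,
        })
    summary = summarize(results)
    rows.append({
        "track_id": "POPULATION", "n_points": summary["n_tracks"],
        "vsl": summary["mean_vsl"], "vcl": summary["mean_vcl"],
        "vap": summary["mean_vap"], "lin": summary["mean_lin"],
        "wob": summary["mean_wob"], "str": summary["mean_str"],
        "alh_mean": summary["mean_alh_mean"], "alh_max": summary["mean_alh_max"],
        "bcf": summary["mean_bcf"], "dnc": summary["mean_dnc"],
        "mad": summary["mean_mad"], "fd": summary["mean_fd"],
        "motile": summary["pct_motile"], "progressive": summary["pct_progressive"],
    })
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def write_json(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
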