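"""Kinematic parameters of a tracked cell.

For a trajectory {p_t}, t = 1..N, sampled at ``fps`` frames/s with scale µ
(µm/px), and its average path {q_t} (rectangular moving average of width w,
length N − w + 1):

* VSL = D(p_1, p_N) · fps/(N−1) · µ        straight-line velocity
* VCL = Σ D(p_t, p_{t+1}) · fps/(N−1) · µ  curvilinear velocity
* VAP = Σ D(q_t, q_{t+1}) · fps/(N−w) · µ  average-path velocity
* LIN = VSL/VCL·100, WOB = VAP/VCL·100, STR = VSL/VAP·100
* ALH: twice the lateral excursion of the raw path about the average path,
  read off at strict local maxima of the midpoint-to-nearest-raw-segment
  distance series (mean and max reported).
* BCF: number of proper crossings between raw-path segments and average-path
  segments, · fps/(N−w), in Hz.
* MAD: mean absolute turning angle of the Δ-lagged direction series
  (degrees).  A "literal" mode returning the plain mean of the direction
  angles is available for comparison with other implementations.
* FD: Katz fractal dimension log(n)/(log(n) + log(d/L)) with n = N−1,
  d = max distance from the first point, L = curvilinear length.
* DNC = VCL · ALH_mean.

Undefined ratios (zero denominators) are reported as NaN and excluded from
population means of that parameter only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisSettings
from .tracks import Trajectory

__all__ = [
    "KinematicsResult",
    "average_path",
    "velocities",
    "ratios",
    "alh",
    "bcf",
    "mad",
    "fractal_dimension",
    "dnc",
    "classify",
    "analyze_track",
    "summarize",
]


@dataclass
class KinematicsResult:
    track_id: int
    n_points: int
    vsl: float
    vcl: float
    vap: float
    lin: float
    wob: float
    str_: float
    alh_mean: float
    alh_max: float
    bcf: float
    dnc: float
    mad: float
    fd: float
    motile: bool
    progressive: bool


def average_path(traj: Trajectory | np.ndarray, w: int) -> np.ndarray:
    """Rectangular moving average of width ``w``; returns (N − w + 1, 2)."""
    pts = traj.points if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    n = len(pts)
    if not 2 <= w <= n - 1:
        raise ValueError(f"window size must lie in [2, {n - 1}], got {w}")
    c = np.cumsum(np.vstack([[0.0, 0.0], pts]), axis=0)
    return (c[w:] - c[:-w]) / w


def _seg_lengths(pts: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def velocities(
    traj: Trajectory, path: np.ndarray, settings: AnalysisSettings
) -> tuple[float, float, float]:
    """(VSL, VCL, VAP) in µm/s."""
    pts = traj.points
    n = len(pts)
    w = n - len(path) + 1
    mu, fps = settings.um_per_px, settings.fps
    vsl = np.linalg.norm(pts[-1] - pts[0]) * fps / (n - 1) * mu
    vcl = _seg_lengths(pts).sum() * fps / (n - 1) * mu
    vap = _seg_lengths(path).sum() * fps / (n - w) * mu
    return float(vsl), float(vcl), float(vap)


def ratios(vsl: float, vcl: float, vap: float) -> tuple[float, float, float]:
    """(LIN, WOB, STR) in percent; NaN where the denominator vanishes."""
    lin = 100.0 * vsl / vcl if vcl > 0 else np.nan
    wob = 100.0 * vap / vcl if vcl > 0 else np.nan
    str_ = 100.0 * vsl / vap if vap > 0 else np.nan
    return lin, wob, str_


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from point p to the closed segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def lateral_distances(pts: np.ndarray, path: np.ndarray, w: int) -> np.ndarray:
    """Distance from each average-path segment midpoint to the nearest raw
    segment drawn from the window p_t..p_{t+w−1} that produced it.

    Series index t runs over average-path segments (length N − w).
    """
    m = len(path)
    out = np.empty(m - 1)
    for t in range(m - 1):
        qm = 0.5 * (path[t] + path[t + 1])
        best = np.inf
        for j in range(t, t + w - 1):
            d = _point_segment_distance(qm, pts[j], pts[j + 1])
            if d < best:
                best = d
        out[t] = best
    return out


def alh(traj: Trajectory, path: np.ndarray, mu: float) -> tuple[float, float]:
    """(ALH_mean, ALH_max) in µm.

    Scans the lateral-distance series for strict local maxima (greater than
    both neighbours); each such peak contributes twice its distance (the
    peak-to-trough excursion).  With no peaks — e.g. a perfectly straight
    track — both values are 0 so that DNC stays defined.
    """
    pts = traj.points
    w = len(pts) - len(path) + 1
    d = lateral_distances(pts, path, w)
    if len(d) < 3:
        return 0.0, 0.0
    interior = d[1:-1]
    peaks = interior[(interior > d[:-2]) & (interior > d[2:])]
    if peaks.size == 0:
        return 0.0, 0.0
    return float(2.0 * mu * peaks.mean()), float(2.0 * mu * peaks.max())


def _proper_crossings(segs_a: np.ndarray, segs_b: np.ndarray) -> int:
    """Count transversal intersections between two segment sets.

    ``segs_a``: (n, 2, 2), ``segs_b``: (m, 2, 2).  Collinear overlaps and
    shared-endpoint touches do not count: both straddle tests must be
    strictly opposite-signed.
    """
    a1 = segs_a[:, None, 0, :]
    a2 = segs_a[:, None, 1, :]
    b1 = segs_b[None, :, 0, :]
    b2 = segs_b[None, :, 1, :]

    def cross(o, p, q):
        return (p[..., 0] - o[..., 0]) * (q[..., 1] - o[..., 1]) - (
            p[..., 1] - o[..., 1]
        ) * (q[..., 0] - o[..., 0])

    d1 = cross(b1, b2, a1)
    d2 = cross(b1, b2, a2)
    d3 = cross(a1, a2, b1)
    d4 = cross(a1, a2, b2)
    return int(np.count_nonzero((d1 * d2 < 0) & (d3 * d4 < 0)))


def bcf(traj: Trajectory, path: np.ndarray, settings: AnalysisSettings) -> float:
    """Beat-cross frequency in Hz: raw-path / average-path crossings · fps/(N−w)."""
    pts = traj.points
    n = len(pts)
    w = n - len(path) + 1
    raw = np.stack([pts[:-1], pts[1:]], axis=1)
    avg = np.stack([path[:-1], path[1:]], axis=1)
    return _proper_crossings(raw, avg) * settings.fps / (n - w)


def mad(traj: Trajectory, delta: int = 1, mode: str = "turning") -> float:
    """Mean angular displacement in degrees.

    ``mode="turning"`` (default): mean absolute wrapped difference between
    consecutive directions of the Δ-lagged displacement vectors — the
    trajectory's mean turning angle.  ``mode="literal"``: plain mean of the
    direction angles themselves, provided for cross-implementation
    comparison.  Zero-length displacements are skipped.
    """
    disp = traj.displacements(delta)
    lengths = np.linalg.norm(disp, axis=1)
    disp = disp[lengths > 0]
    if len(disp) == 0:
        return np.nan
    angles = np.arctan2(disp[:, 1], disp[:, 0])
    if mode == "literal":
        return float(np.degrees(angles.mean()))
    if mode != "turning":
        raise ValueError('mode must be "turning" or "literal"')
    if len(angles) < 2:
        return np.nan
    turns = np.diff(angles)
    turns = np.mod(turns + np.pi, 2.0 * np.pi) - np.pi
    return float(np.degrees(np.abs(turns).mean()))


def fractal_dimension(traj: Trajectory) -> float:
    """Katz fractal dimension; NaN for a stationary track (d = 0)."""
    pts = traj.points
    n = len(pts) - 1
    if n < 2:
        return np.nan
    d = float(np.linalg.norm(pts - pts[0], axis=1).max())
    length = float(_seg_lengths(pts).sum())
    if d == 0.0 or length == 0.0:
        return np.nan
    return float(np.log(n) / (np.log(n) + np.log(d / length)))


def dnc(vcl: float, alh_mean: float) -> float:
    """Dance: VCL · ALH_mean, µm²/s."""
    return vcl * alh_mean


def classify(
    traj: Trajectory,
    vcl: float,
    str_: float,
    vap: float,
    settings: AnalysisSettings,
) -> tuple[bool, bool]:
    """(motile, progressive) flags; all comparisons strict."""
    moved = not np.array_equal(traj.points[0], traj.points[-1])
    motile = bool(vcl > settings.min_vcl and moved)
    progressive = bool(
        motile
        and not np.isnan(str_)
        and str_ > settings.str_threshold
        and vap > settings.vap_threshold
    )
    return motile, progressive


def analyze_track(
    traj: Trajectory, settings: AnalysisSettings, mad_mode: str = "turning"
) -> KinematicsResult:
    """Compute every kinematic parameter for one trajectory."""
    path = average_path(traj, settings.window_size)
    vsl, vcl, vap = velocities(traj, path, settings)
    lin, wob, str_ = ratios(vsl, vcl, vap)
    alh_mean, alh_max = alh(traj, path, settings.um_per_px)
    motile, progressive = classify(traj, vcl, str_, vap, settings)
    return KinematicsResult(
        track_id=traj.track_id,
        n_points=len(traj),
        vsl=vsl,
        vcl=vcl,
        vap=vap,
        lin=lin,
        wob=wob,
        str_=str_,
        alh_mean=alh_mean,
        alh_max=alh_max,
        bcf=bcf(traj, path, settings),
        dnc=dnc(vcl, alh_mean),
        mad=mad(traj, settings.angle_delta, mode=mad_mode),
        fd=fractal_dimension(traj),
        motile=motile,
        progressive=progressive,
    )


def summarize(results: list[KinematicsResult]) -> dict:
    """Population summary: means over motile tracks, % motile, % progressive.

    NaN entries (undefined ratios) are excluded from the mean of that
    parameter only.
    """
    n = len(results)
    motile = [r for r in results if r.motile]
    out = {
        "n_tracks": n,
        "pct_motile": 100.0 * len(motile) / n if n else np.nan,
        "pct_progressive": 100.0 * sum(r.progressive for r in results) / n if n else np.nan,
    }
    fields = ["vsl", "vcl", "vap", "lin", "wob", "str_", "alh_mean", "alh_max",
              "bcf", "dnc", "mad", "fd"]
    for f in fields:
        vals = np.array([getattr(r, f) for r in motile], dtype=float)
        vals = vals[~np.isnan(vals)]
        out["mean_" + f.rstrip("_")] = float(vals.mean()) if vals.size else np.nan
    return out
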