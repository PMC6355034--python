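"""Directional-bias statistics for track populations.

The instantaneous directionality angle ψ of a displacement is its signed
angle relative to the stimulus gradient direction θ, wrapped to
(−180°, 180°].  Displacements with ψ in the closed cone [−γ, +γ] count as
oriented toward the gradient (N⁺); displacements counted against it (N⁻)
depend on the chosen option:

* option 1: everything outside [−γ, +γ];
* option 2: only the opposite cone, |ψ| ≥ 180° − γ.

The ch-index is 100·N⁺/(N⁺+N⁻).  A sample's odds value is N⁺/N⁻ and the
odds ratio (O.R.) of a test sample over a control sample is the bias
statistic.  Its null distribution is built by bootstrap: pooled control
trajectories are repeatedly split into two disjoint random subsets, each
subset's pooled odds computed, and their ratio recorded; the decision
threshold is the 95th percentile of that distribution, giving a ≈5 %
type-I error for calls of directional bias.

Angles are pooled across all trajectories of a sample before counting:
N⁺ and N⁻ are population totals, not per-track averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisSettings
from .tracks import Trajectory, TrackSet

__all__ = [
    "AngleSample",
    "ORDistribution",
    "directionality_angles",
    "pooled_angles",
    "count_oriented",
    "ch_index",
    "odds_value",
    "or_ratio",
    "bootstrap_threshold",
    "is_chemotactic",
    "rose_histogram",
]


def directionality_angles(traj: Trajectory, delta: int, theta_deg: float) -> np.ndarray:
    """ψ angles (degrees, wrapped to (−180, 180]) of the Δ-lagged displacements.

    Zero-length displacements carry no direction and are skipped.
    """
    disp = traj.displacements(delta)
    lengths = np.linalg.norm(disp, axis=1)
    disp = disp[lengths > 0]
    if disp.size == 0:
        return np.empty(0)
    ang = np.degrees(np.arctan2(disp[:, 1], disp[:, 0])) - theta_deg
    ang = np.mod(ang + 180.0, 360.0) - 180.0
    ang[ang == -180.0] = 180.0
    return ang


def pooled_angles(tracks: TrackSet, settings: AnalysisSettings) -> np.ndarray:
    """All ψ angles of a track population, pooled in track order."""
    parts = [
        directionality_angles(t, settings.angle_delta, settings.theta)
        for t in tracks
        if len(t) > settings.angle_delta
    ]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def count_oriented(psis: np.ndarray, gamma: float, option: int) -> tuple[int, int]:
    """(N⁺, N⁻) for a pooled angle sample; interval endpoints are inclusive."""
    if not 0 < gamma <= 90:
        raise ValueError("gamma must be in (0, 90] degrees")
    psis = np.asarray(psis, dtype=float)
    toward = np.abs(psis) <= gamma
    n_plus = int(np.count_nonzero(toward))
    if option == 1:
        n_minus = psis.size - n_plus
    elif option == 2:
        n_minus = int(np.count_nonzero(np.abs(psis) >= 180.0 - gamma))
    else:
        raise ValueError("option must be 1 or 2")
    return n_plus, n_minus


@dataclass
class AngleSample:
    """Pooled directionality angles of one sample with their oriented counts."""

    psis: np.ndarray
    n_plus: int
    n_minus: int

    @classmethod
    def from_psis(cls, psis: np.ndarray, gamma: float, option: int) -> "AngleSample":
        n_plus, n_minus = count_oriented(psis, gamma, option)
        return cls(psis=np.asarray(psis, dtype=float), n_plus=n_plus, n_minus=n_minus)

    @classmethod
    def from_tracks(cls, tracks: TrackSet, settings: AnalysisSettings) -> "AngleSample":
        return cls.from_psis(pooled_angles(tracks, settings), settings.gamma, settings.option)


def ch_index(n_plus: int, n_minus: int) -> float:
    """100·N⁺/(N⁺+N⁻); NaN when no displacement was counted."""
    total = n_plus + n_minus
    if total == 0:
        return np.nan
    return 100.0 * n_plus / total


def odds_value(n_plus: int, n_minus: int) -> float:
    """N⁺/N⁻; NaN when N⁻ = 0."""
    if n_minus == 0:
        return np.nan
    return n_plus / n_minus


def or_ratio(test: AngleSample, control: AngleSample) -> float:
    """Odds ratio of the test sample over the control sample; NaN if undefined."""
    num = odds_value(test.n_plus, test.n_minus)
    den = odds_value(control.n_plus, control.n_minus)
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return np.nan
    return num / den


@dataclass
class ORDistribution:
    """Bootstrap sample of null O.R. values and its P95 decision threshold."""

    ratios: np.ndarray
    threshold: float

    @classmethod
    def from_ratios(cls, ratios: np.ndarray) -> "ORDistribution":
        ratios = np.asarray(ratios, dtype=float)
        return cls(ratios=ratios, threshold=float(np.percentile(ratios, 95)))


def _per_track_counts(
    controls: list[TrackSet], settings: AnalysisSettings
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    plus, minus, sizes = [], [], []
    for ts in controls:
        k = 0
        for traj in ts:
            if len(traj) <= settings.angle_delta:
                continue
            psis = directionality_angles(traj, settings.angle_delta, settings.theta)
            p, m = count_oriented(psis, settings.gamma, settings.option)
            plus.append(p)
            minus.append(m)
            k += 1
        sizes.append(k)
    return np.array(plus, dtype=float), np.array(minus, dtype=float), sizes


def bootstrap_threshold(
    controls: TrackSet | list[TrackSet],
    settings: AnalysisSettings,
    n_resamples: int | None = None,
    seed: int | None = None,
    subset_size: int | None = None,
) -> ORDistribution:
    """Bootstrap the null O.R. distribution from control (no-stimulus) tracks.

    Each iteration draws two disjoint random subsets of ``subset_size``
    trajectories from the pool (trajectories are returned to the pool between
    iterations), computes each subset's pooled odds N⁺/N⁻ and records their
    ratio.  The decision threshold is the 95th percentile of the recorded
    ratios.

    ``subset_size`` defaults to the mean number of usable trajectories per
    control recording, so that the null spread matches the sampling
    variability of one recording-vs-recording comparison; when a single
    pooled recording is supplied it falls back to half the pool.  Iterations
    where a subset has zero N⁺ or N⁻ are redrawn (capped at 100·n_resamples
    attempts).
    """
    if isinstance(controls, TrackSet):
        controls = [controls]
    if n_resamples is None:
        n_resamples = settings.n_resamples
    plus, minus, sizes = _per_track_counts(controls, settings)
    n = plus.size
    if n < 4:
        raise ValueError("need at least 4 pooled control trajectories")
    if subset_size is None:
        if len(sizes) > 1:
            subset_size = int(round(np.mean(sizes)))
        else:
            subset_size = n // 2
    subset_size = max(subset_size, 2)
    if 2 * subset_size > n:
        raise ValueError(
            f"subset_size {subset_size} too large for a pool of {n} trajectories"
        )

    rng = np.random.default_rng(seed)
    ratios = np.empty(n_resamples)
    attempts = 0
    i = 0
    while i < n_resamples:
        attempts += 1
        if attempts > 100 * n_resamples:
            raise RuntimeError("too many degenerate bootstrap iterations")
        perm = rng.permutation(n)
        h1, h2 = perm[:subset_size], perm[subset_size : 2 * subset_size]
        p1, m1 = plus[h1].sum(), minus[h1].sum()
        p2, m2 = plus[h2].sum(), minus[h2].sum()
        if m1 == 0 or m2 == 0 or p2 == 0:
            continue  # degenerate split: redraw
        ratios[i] = (p1 / m1) / (p2 / m2)
        i += 1
    return ORDistribution.from_ratios(ratios)


def is_chemotactic(or_value: float, dist: ORDistribution) -> bool:
    """Directional bias is called when the O.R. strictly exceeds the P95 threshold."""
    return bool(np.isfinite(or_value) and or_value > dist.threshold)


def rose_histogram(psis: np.ndarray, bin_deg: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Angle histogram over (−180, 180] with ``bin_deg``-wide bins.

    Returns (counts, bin_edges) suitable for a rose plot.
    """
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(psis, bins=edges)
    return counts, edges
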