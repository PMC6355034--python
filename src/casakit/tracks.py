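"""Trajectory containers shared by the simulator, tracker and analysis modules.

A :class:`Trajectory` is the ordered sequence of head-centroid positions of one
cell, in pixel coordinates (image convention: origin top-left, x rightward,
y downward), together with the video frame index of every point.  Frame indices
are required to be consecutive: the tracker never bridges a missed detection,
so a gap always starts a new track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Trajectory", "TrackSet"]


@dataclass
class Trajectory:
    """Ordered (x, y) positions of one cell over consecutive frames.

    Parameters
    ----------
    track_id : int
        Identifier, unique within a :class:`TrackSet`.
    points : (N, 2) ndarray
        Sub-pixel centroid positions, columns ``(x, y)`` in pixels.
    frames : (N,) ndarray
        0-based frame index of each point; strictly consecutive.
    responsive : bool, optional
        For simulated cells: whether the field-alignment term was applied.
    """

    track_id: int
    points: np.ndarray
    frames: np.ndarray
    responsive: bool | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.frames.shape != (self.points.shape[0],):
            raise ValueError("frames must align with points")
        if len(self.points) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.diff(self.frames) == 1):
            raise ValueError("frame indices must be strictly consecutive")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def displacements(self, delta: int = 1) -> np.ndarray:
        """Vectors from each point to the point ``delta`` frames later, (N-delta, 2)."""
        if not 1 <= delta <= len(self) - 1:
            raise ValueError(f"delta must be in [1, {len(self) - 1}]")
        return self.points[delta:] - self.points[:-delta]


@dataclass
class TrackSet:
    """A collection of trajectories from one recording or simulation."""

    trajectories: list[Trajectory] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def n_frames(self) -> int:
        """Highest frame index seen plus one (0 for an empty set)."""
        if not self.trajectories:
            return 0
        return int(max(t.frames[-1] for t in self.trajectories)) + 1
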