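"""Persistent-random-walk simulator for sperm-like cell populations.

Each virtual cell carries a swimming angle ψ that diffuses with rotational
diffusion coefficient ``D_rot`` and, for "responsive" (capacitated) cells,
relaxes toward an external field parallel to the +x axis at rate β/τ:

    ψ' = ψ − (β/τ)·sin(ψ)·dt + √(2·D_rot·dt)·z,   z ~ N(0, 1)
    x' = x + v0·cos(ψ')·dt
    y' = y + v0·sin(ψ')·dt

with dt fixed at one frame, so all rates are per frame and lengths in pixels.
The Euler step updates the angle first and moves the cell along the updated
angle, so every step has length exactly ``v0``.  β > 0 attracts cells toward
the +x direction; β = 0 is a neutral (non-chemotactic) population.

Cells start uniformly inside the arena and are free to leave it; positions
are clipped only when rendering frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .tracks import Trajectory, TrackSet

__all__ = ["SimulationParams", "CellState", "step_cell", "simulate_population", "render_frames"]


def wrap_angle(psi):
    """Wrap angle(s) to (−π, π]."""
    w = np.mod(np.asarray(psi) + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if np.isscalar(psi) else w


@dataclass
class SimulationParams:
    """Parameters of the persistent-random-walk population.

    Units: pixels and frames throughout (dt = 1 frame).

    ``responsiveness`` is the fraction of cells subject to the alignment term,
    mimicking the capacitated subpopulation; ``psi0`` is the initial swimming
    angle in radians, or ``"uniform"`` for angles drawn uniformly on the
    circle.  ``cell_axes`` are the ellipse *semi*-axes (major, minor) used
    when rendering, so the default (5, 4) paints a 10×8 px cell.
    """

    D_rot: float = 0.1
    v0: float = 3.0
    beta: float = 0.0
    tau: float = 1.0
    responsiveness: float = 0.0
    psi0: Union[float, str] = "uniform"
    n_cells: int = 100
    n_frames: int = 500
    arena_w: int = 800
    arena_h: int = 800
    cell_axes: tuple[float, float] = (5.0, 4.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D_rot < 0:
            raise ValueError("D_rot must be >= 0")
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 <= self.responsiveness <= 1:
            raise ValueError("responsiveness must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if isinstance(self.psi0, str) and self.psi0 != "uniform":
            raise ValueError('psi0 must be an angle in radians or "uniform"')

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class CellState:
    """Position and swimming angle of one cell; psi wrapped to (−π, π]."""

    x: float
    y: float
    psi: float

    def __post_init__(self) -> None:
        self.psi = wrap_angle(self.psi)


def step_cell(state: CellState, params: SimulationParams, responsive: bool, rng) -> CellState:
    """Advance one cell by a single Euler step of one frame.

    The alignment term is applied only when ``responsive`` is true; the
    displacement uses the updated angle, so its length is exactly ``v0``.
    """
    beta_eff = params.beta if responsive else 0.0
    noise = np.sqrt(2.0 * params.D_rot) * rng.standard_normal()
    psi = wrap_angle(state.psi - (beta_eff / params.tau) * np.sin(state.psi) + noise)
    return CellState(
        x=state.x + params.v0 * np.cos(psi),
        y=state.y + params.v0 * np.sin(psi),
        psi=psi,
    )


def simulate_population(params: SimulationParams) -> TrackSet:
    """Simulate ``n_cells`` persistent random walks of ``n_frames`` points.

    The first ``floor(responsiveness * n_cells)`` cells are responsive (the
    alignment rate β/τ applies); the rest behave as β = 0.  Initial positions
    are uniform inside the arena.  Reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    n_resp = int(np.floor(params.responsiveness * n))
    responsive = np.zeros(n, dtype=bool)
    responsive[:n_resp] = True
    beta_eff = np.where(responsive, params.beta, 0.0)

    pos = np.empty((params.n_frames, n, 2))
    pos[0, :, 0] = rng.uniform(0.0, params.arena_w, n)
    pos[0, :, 1] = rng.uniform(0.0, params.arena_h, n)
    if isinstance(params.psi0, str):
        psi = rng.uniform(-np.pi, np.pi, n)
    else:
        psi = np.full(n, wrap_angle(float(params.psi0)))

    sigma = np.sqrt(2.0 * params.D_rot)
    for t in range(1, params.n_frames):
        psi = wrap_angle(psi - (beta_eff / params.tau) * np.sin(psi) + sigma * rng.standard_normal(n))
        pos[t, :, 0] = pos[t - 1, :, 0] + params.v0 * np.cos(psi)
        pos[t, :, 1] = pos[t - 1, :, 1] + params.v0 * np.sin(psi)

    frames = np.arange(params.n_frames)
    trajectories = [
        Trajectory(track_id=i, points=np.ascontiguousarray(pos[:, i, :]),
                   frames=frames, responsive=bool(responsive[i]))
        for i in range(n)
    ]
    return TrackSet(trajectories, meta={"params": params, "source": "simulation"})


def render_frames(tracks: TrackSet, params: SimulationParams) -> np.ndarray:
    """Paint trajectories as bright ellipses on a dark 8-bit frame stack.

    Returns a ``(n_frames, arena_h, arena_w)`` uint8 array.  Each cell is a
    filled 255-valued ellipse with semi-axes ``params.cell_axes`` centred on
    its position, major axis along its current swimming direction (taken from
    the local displacement).  Cells outside the arena are clipped and vanish
    once fully out of frame.
    """
    major, minor = params.cell_axes
    h, w = params.arena_h, params.arena_w
    if 2 * max(major, minor) >= min(h, w):
        raise ValueError("arena is smaller than the rendered cell")
    n_frames = tracks.n_frames
    stack = np.zeros((n_frames, h, w), dtype=np.uint8)
    for traj in tracks:
        pts = traj.points
        # heading per point: direction of the step into the point
        d = np.diff(pts, axis=0)
        headings = np.arctan2(d[:, 1], d[:, 0])
        headings = np.concatenate([headings[:1], headings])
        for frame, (x, y), psi in zip(traj.frames, pts, headings):
            rr, cc = _draw_ellipse(y, x, minor, major, shape=(h, w), rotation=-psi)
            stack[frame, rr, cc] = 255
    return stack
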