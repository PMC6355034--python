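"""Analysis settings and YAML configuration loading.

All user-tunable thresholds of the analysis pipeline live in
:class:`AnalysisSettings`.  Defaults follow common CASA practice for 60 fps
recordings: a cell is motile above a VCL of 10 µm/s and progressive when
STR > 80 % and VAP > 25 µm/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisSettings", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file or settings object is invalid."""


@dataclass
class AnalysisSettings:
    """User thresholds for detection, tracking, kinematics and chemotaxis.

    Attributes
    ----------
    um_per_px : float
        Spatial scale µ, microns per pixel.
    fps : float
        Frame rate of the recording (frames/s); overrides container metadata.
    min_cell_size, max_cell_size : float
        Accepted blob area window, µm².
    min_vcl : float
        Motility threshold on curvilinear velocity, µm/s.
    min_track_length : int
        Tracks shorter than this many frames are discarded.
    max_displacement : float
        Search radius for frame-to-frame linking, µm. A cell is never linked
        to a detection farther than this from its last position.
    window_size : int
        Width w (frames) of the rectangular moving average defining the
        average path; must satisfy 2 <= w <= N - 1 for a track of length N.
    str_threshold : float
        STR (%) above which a motile track counts as progressive.
    vap_threshold : float
        VAP (µm/s) above which a motile track counts as progressive.
    vcl_lower, vcl_upper : float
        Reporting bands (µm/s) used to colour trajectories as slow /
        moderate / fast in overlay output.
    angle_delta : int
        Frame lag Δ used for directionality and turning angles.
    gamma : float
        Half-width γ (degrees) of the gradient cone, 0 < γ <= 90.
    theta : float
        Gradient direction θ (degrees, image frame: 0 = +x, angles follow
        atan2(dy, dx) with y downward).
    option : int
        How displacements not pointing along the gradient are counted:
        1 = everything outside [-γ, +γ]; 2 = only the opposite cone.
    n_resamples : int
        Bootstrap iterations for the O.R. null distribution.
    foreground : str
        "bright" for fluorescence/synthetic frames (cells brighter than
        background), "dark" for bright-field stains.
    """

    um_per_px: float = 1.0
    fps: float = 60.0
    min_cell_size: float = 10.0
    max_cell_size: float = 1000.0
    min_vcl: float = 10.0
    min_track_length: int = 10
    max_displacement: float = 10.0
    window_size: int = 5
    str_threshold: float = 80.0
    vap_threshold: float = 25.0
    vcl_lower: float = 25.0
    vcl_upper: float = 75.0
    angle_delta: int = 1
    gamma: float = 30.0
    theta: float = 0.0
    option: int = 1
    n_resamples: int = 10000
    foreground: str = "bright"

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.min_cell_size < 0 or self.max_cell_size < self.min_cell_size:
            raise ConfigError("cell size window must satisfy 0 <= min <= max")
        if self.min_track_length < 1:
            raise ConfigError("min_track_length must be at least 1 frame")
        if self.max_displacement <= 0:
            raise ConfigError("max_displacement must be positive")
        if self.window_size < 2:
            raise ConfigError("window_size must be at least 2")
        if self.angle_delta < 1:
            raise ConfigError("angle_delta must be at least 1")
        if not 0 < self.gamma <= 90:
            raise ConfigError("gamma must be in (0, 90] degrees")
        if self.option not in (1, 2):
            raise ConfigError("option must be 1 or 2")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be at least 1")
        if self.foreground not in ("bright", "dark"):
            raise ConfigError('foreground must be "bright" or "dark"')

    def validate_for_video(self, n_frames: int) -> None:
        """Check the frame-count-dependent range rules before any computation."""
        if self.min_track_length > n_frames:
            raise ConfigError(
                f"min_track_length ({self.min_track_length}) exceeds the video "
                f"length ({n_frames} frames)"
            )
        if not 2 <= self.window_size <= n_frames - 1:
            raise ConfigError(
                f"window_size must lie in [2, {n_frames - 1}] for a "
                f"{n_frames}-frame video"
            )
        if not 1 <= self.angle_delta <= n_frames - 2:
            raise ConfigError(
                f"angle_delta must lie in [1, {n_frames - 2}] for a "
                f"{n_frames}-frame video"
            )

    @property
    def max_displacement_px(self) -> float:
        return self.max_displacement / self.um_per_px

    def replace(self, **kwargs) -> "AnalysisSettings":
        return dataclasses.replace(self, **kwargs)


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> dict:
    """Load a YAML config with optional ``analysis`` and ``simulation`` sections.

    Returns a dict with keys ``analysis`` (:class:`AnalysisSettings`) and
    ``simulation`` (:class:`~casakit.simulate.SimulationParams` or None).
    Unknown keys anywhere are rejected.
    """
    from .simulate import SimulationParams  # local import avoids a cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"analysis", "simulation"}
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    analysis = _build(AnalysisSettings, raw.get("analysis") or {}, "analysis")
    simulation = None
    if "simulation" in raw:
        simulation = _build(SimulationParams, raw.get("simulation") or {}, "simulation")
    return {"analysis": analysis, "simulation": simulation}
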