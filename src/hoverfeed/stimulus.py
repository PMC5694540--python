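"""Angular geometry of projected visual stimuli seen by a docked bird.

The experimental rig back-projects a pattern (square-wave grating or random
dot-field) onto a screen a fixed distance in front of the feeder.  The
functions here convert between physical screen coordinates and visual angles
at the bird's eye, and render deterministic dot-field motion sequences.

Two conventions coexist on purpose: the *whole-surface* angular extent uses
the exact ``2*atan(w / 2d)`` form, while on-screen sizes (dot diameters,
translation distances) use the small-angle linear pixel-to-degree mapping.
The rig's printed numbers (90 deg field, 3.4 deg dots) come from exactly this
pair of conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator, Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "angular_extent",
    "grating_spatial_frequency",
    "pixels_to_degrees",
    "translation_angular_speed",
    "translation_angular_speed_linear",
    "render_dotfield_frames",
    "dotfield_frames_to_dataframe",
]

PatternKind = Literal["grating", "dotfield"]
MotionDirection = Literal["left", "right", "up", "down", "none"]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one projected background pattern.

    Defaults describe the rig's dot-field: 250 black dots of 40 px diameter
    on a 1050 px / 0.5 m screen viewed from 0.25 m, covering ~90 deg of the
    frontal visual field.
    """

    kind: PatternKind = "dotfield"
    n_cycles: Optional[int] = None          # gratings only
    n_dots: int = 250
    dot_diameter_px: float = 40.0
    screen_width_m: float = 0.5
    screen_px: int = 1050
    viewing_distance_m: float = 0.25
    motion_direction: MotionDirection = "none"
    motion_speed_deg_s: float = 0.0

    def __post_init__(self) -> None:
        if self.screen_px <= 0:
            raise ValueError("screen_px must be positive")
        if self.viewing_distance_m <= 0:
            raise ValueError("viewing_distance_m must be positive")
        if self.motion_speed_deg_s < 0:
            raise ValueError("motion_speed_deg_s must be >= 0")
        if self.kind == "grating" and (self.n_cycles is None or self.n_cycles < 1):
            raise ValueError("gratings require n_cycles >= 1")

    @property
    def extent_deg(self) -> float:
        """Whole-screen angular extent at the viewing position."""
        return angular_extent(self.screen_width_m, self.viewing_distance_m)

    @property
    def deg_per_px(self) -> float:
        return self.extent_deg / self.screen_px

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


def angular_extent(width_m: float, distance_m: float) -> float:
    """Angular extent (deg) of a flat surface of ``width_m`` centered on the
    viewing axis at ``distance_m``.

    Uses the exact perspective form ``2 * atan(width / (2 * distance))``.
    """
    if width_m <= 0 or distance_m <= 0:
        raise ValueError("width and distance must be positive")
    return float(np.degrees(2.0 * np.arctan2(width_m / 2.0, distance_m)))


def grating_spatial_frequency(n_cycles: int, extent_deg: float) -> float:
    """Spatial frequency (cycles/deg) of a grating of ``n_cycles`` spanning
    ``extent_deg`` of visual angle."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if extent_deg <= 0:
        raise ValueError("extent_deg must be positive")
    return float(n_cycles) / float(extent_deg)


def pixels_to_degrees(extent_px: float, screen_px: int, screen_extent_deg: float) -> float:
    """Linear (small-angle) pixel-to-degree conversion for on-screen sizes."""
    if screen_px <= 0:
        raise ValueError("screen_px must be positive")
    return float(extent_px) * float(screen_extent_deg) / float(screen_px)


def translation_angular_speed(speed_m_s: float, distance_m: float) -> float:
    """Instantaneous angular speed (deg/s) of a target translating at
    ``speed_m_s`` perpendicular to the line of sight at ``distance_m``.

    Uses the exact instantaneous geometry ``v / d`` radians per second.
    """
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    return float(np.degrees(speed_m_s / distance_m))


def translation_angular_speed_linear(
    speed_m_s: float, screen_width_m: float, screen_px: int, screen_extent_deg: float
) -> float:
    """Angular speed via the on-screen linear pixel mapping.

    Alternative to :func:`translation_angular_speed`; converts the physical
    speed to px/s on the screen, then px to degrees linearly.  The two
    conventions differ by a few deg/s for the rig geometry and both are
    exposed because neither is singled out by the experimental description.
    """
    if screen_width_m <= 0:
        raise ValueError("screen width must be positive")
    px_per_s = speed_m_s / screen_width_m * screen_px
    return pixels_to_degrees(px_per_s, screen_px, screen_extent_deg)


_DIRECTION_VECTORS = {
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
    "up": (0.0, -1.0),   # screen coordinates: y grows downward
    "down": (0.0, 1.0),
    "none": (0.0, 0.0),
}


def render_dotfield_frames(
    spec: StimulusSpec,
    duration_s: float,
    seed: int,
    frame_rate_hz: float = 60.0,
) -> np.ndarray:
    """Render a deterministic dot-field motion sequence.

    Dots are positioned uniformly at random on the screen, translate rigidly
    at the spec's speed and direction, have infinite lifetimes, and wrap to a
    uniformly random position on the upstream edge when they exit the field.

    Returns an array of shape ``(n_frames, n_dots, 2)`` of pixel coordinates.
    The same ``seed`` always yields a bitwise-identical sequence.
    """
    if spec.kind != "dotfield":
        raise ValueError("render_dotfield_frames requires a dotfield spec")
    rng = np.random.default_rng(seed)
    n_frames = max(1, int(round(duration_s * frame_rate_hz)))
    w = float(spec.screen_px)
    pos = rng.uniform(0.0, w, size=(spec.n_dots, 2))

    px_per_deg = spec.screen_px / spec.extent_deg
    dx, dy = _DIRECTION_VECTORS[spec.motion_direction]
    step = spec.motion_speed_deg_s * px_per_deg / frame_rate_hz
    vel = np.array([dx * step, dy * step])

    frames = np.empty((n_frames, spec.n_dots, 2))
    frames[0] = pos
    for i in range(1, n_frames):
        pos = pos + vel
        # Regenerate dots that left the field on the upstream edge, with a
        # fresh uniform transverse coordinate.
        for axis, v in enumerate(vel):
            if v > 0:
                out = pos[:, axis] >= w
                pos[out, axis] = pos[out, axis] - w
                pos[out, 1 - axis] = rng.uniform(0.0, w, size=int(out.sum()))
            elif v < 0:
                out = pos[:, axis] < 0
                pos[out, axis] = pos[out, axis] + w
                pos[out, 1 - axis] = rng.uniform(0.0, w, size=int(out.sum()))
        frames[i] = pos
    return frames


def dotfield_frames_to_dataframe(frames: np.ndarray) -> pd.DataFrame:
    """Tidy export of rendered frames: columns frame, dot_id, x_px, y_px."""
    n_frames, n_dots, _ = frames.shape
    frame_idx = np.repeat(np.arange(n_frames), n_dots)
    dot_idx = np.tile(np.arange(n_dots), n_frames)
    flat = frames.reshape(-1, 2)
    return pd.DataFrame(
        {"frame": frame_idx, "dot_id": dot_idx, "x_px": flat[:, 0], "y_px": flat[:, 1]}
    )
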