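"""Deterministic scene setup: framing, camera, 3-point lighting, render
settings and stereoscopic pairs.

The system is framed by the mean position of all critical points (center
``x0,y0,z0``) and the radius ``r`` of the bounding sphere about it.  The
camera sits at ``center + (0, 0, -4r)`` looking at the center; the key
and fill spotlights are the camera position rotated by +-45 degrees about
the vertical axis through the center and raised by ``r`` along +y; a rim
lamp sits directly behind the system at ``center + (0, 0, +4r)``.  All
constructions are equivariant under rigid translation of the topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import TopologyError, as_position

#: Default vertical field of view in degrees.
DEFAULT_FOV = 49.1

#: Key/fill azimuthal offset from the camera direction, degrees.
LIGHT_ROTATION_DEG = 45.0

#: Key, fill and rim energies.  Only the key > fill ordering is
#: essential; the values are configurable.
KEY_ENERGY, FILL_ENERGY, RIM_ENERGY = 1.0, 0.5, 0.8

#: Default stereo half-angle in degrees.
STEREO_HALF_ANGLE = 2.0

SKY_BLUE = (0.53, 0.81, 0.92)


@dataclass
class SceneFrame:
    center: np.ndarray
    extent: float

    def __post_init__(self):
        self.center = as_position(self.center)
        if not self.extent > 0:
            raise TopologyError("frame extent must be positive")


@dataclass
class Camera:
    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    fov_deg: float = DEFAULT_FOV

    def __post_init__(self):
        self.position = as_position(self.position)
        self.look_at = as_position(self.look_at)
        self.up = as_position(self.up)
        if np.allclose(self.position, self.look_at):
            raise TopologyError("camera position must differ from look_at")


@dataclass
class Light:
    kind: str  # "spot" | "lamp"
    position: np.ndarray
    energy: float
    aim: np.ndarray | None = None  # spots only
    color_rgb: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("spot", "lamp"):
            raise TopologyError(f"unknown light kind {self.kind!r}")
        self.position = as_position(self.position)
        if not self.energy > 0:
            raise TopologyError("light energy must be positive")
        if self.kind == "spot":
            if self.aim is None:
                raise TopologyError("spot lights need an aim point")
            self.aim = as_position(self.aim)
            if np.allclose(self.aim, self.position):
                raise TopologyError("spot aim must differ from its position")


@dataclass
class RenderSettings:
    width: int = 1000
    height: int = 1000
    antialias_samples: int = 8
    raytrace_samples: int = 6
    output_format: str = "png"
    color_depth_bits: int = 16
    compression: bool = False
    background_rgb: tuple = SKY_BLUE

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise TopologyError("render resolution must be positive")


def default_render_settings() -> RenderSettings:
    """The stock render block: 1000x1000 px, 8 antialias samples, ray
    tracing with 6 samples, 16-bit png without compression, sky-blue
    background."""
    return RenderSettings()


def compute_frame(cps) -> SceneFrame:
    """Frame = mean CP position and bounding-sphere radius (floored at
    1 bohr so single-CP systems stay framable)."""
    if not len(cps):
        raise TopologyError("cannot frame an empty critical-point list")
    pos = np.array([cp.position for cp in cps])
    center = pos.mean(axis=0)
    extent = float(np.max(np.linalg.norm(pos - center, axis=1)))
    return SceneFrame(center=center, extent=max(extent, 1.0))


def place_camera(frame: SceneFrame, fov_deg: float = DEFAULT_FOV) -> Camera:
    """Camera at center + (0, 0, -4r), looking at the center, +y up."""
    position = frame.center + np.array([0.0, 0.0, -4.0 * frame.extent])
    return Camera(position=position, look_at=frame.center.copy(), fov_deg=fov_deg)


def _rotate_about_vertical(point, center, angle_deg):
    """Rotate about the +y axis through `center`."""
    a = math.radians(angle_deg)
    d = np.asarray(point, dtype=float) - center
    x = d[0] * math.cos(a) + d[2] * math.sin(a)
    z = -d[0] * math.sin(a) + d[2] * math.cos(a)
    return center + np.array([x, d[1], z])


def place_lights(frame: SceneFrame, camera: Camera,
                 key_energy: float = KEY_ENERGY,
                 fill_energy: float = FILL_ENERGY,
                 rim_energy: float = RIM_ENERGY) -> list:
    """Key and fill spots at +-45 deg from the camera, raised by r; rim
    lamp directly behind the system relative to the camera."""
    r = frame.extent
    lift = np.array([0.0, r, 0.0])
    key_pos = _rotate_about_vertical(camera.position, frame.center,
                                     +LIGHT_ROTATION_DEG) + lift
    fill_pos = _rotate_about_vertical(camera.position, frame.center,
                                      -LIGHT_ROTATION_DEG) + lift
    rim_pos = frame.center + np.array([0.0, 0.0, 4.0 * r])
    return [
        Light(kind="spot", position=key_pos, aim=frame.center.copy(),
              energy=key_energy),
        Light(kind="spot", position=fill_pos, aim=frame.center.copy(),
              energy=fill_energy),
        Light(kind="lamp", position=rim_pos, energy=rim_energy),
    ]


def make_stereo_pair(camera: Camera, frame: SceneFrame,
                     half_angle_deg: float = STEREO_HALF_ANGLE):
    """Two cameras rotated +-half_angle about the vertical axis through
    the center, ordered for cross-eyed viewing (the left frame is the
    right-eye view)."""
    if not 0.0 < half_angle_deg <= 10.0:
        raise TopologyError("stereo half-angle must be in (0, 10] degrees")

    def rotated(angle):
        return Camera(
            position=_rotate_about_vertical(camera.position, frame.center, angle),
            look_at=frame.center.copy(),
            up=camera.up.copy(), fov_deg=camera.fov_deg)

    right_eye = rotated(+half_angle_deg)
    left_eye = rotated(-half_angle_deg)
    return right_eye, left_eye
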