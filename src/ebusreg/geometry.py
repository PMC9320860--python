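"""Device-tip geometry of a convex-probe EBUS bronchoscope.

A 6-DOF pose (three Euler angles, one 3D position) fixes the full tip
geometry of the integrated device: the bronchoscope tip axis ``nB``, the
videobronchoscope camera axis ``nC`` (tilted by a fixed angle ``Δ`` from
``nB``), and the ultrasound probe axis ``nUS`` (perpendicular to ``nB``,
with its fan-plane origin ``sUS`` offset a fixed distance along the tip
axis from the tip start point ``sB``).  The 2D fan-shaped scan plane is
spanned by ``nUS`` and an in-plane "up" vector; here up = ``nB``, i.e. the
scan plane contains the scope axis and the fan extends forward of the
probe, matching the physical device.

Conventions (documented, fixed):

* Euler angles are intrinsic Z-Y-X (yaw ``a``, pitch ``b``, roll ``c``),
  in degrees.  Positions are world millimetres.
* In the canonical (identity-pose) body frame the tip axis is +z, the
  probe axis is +x, and the third (right-handed) axis is +y.
* The camera axis is tilted by ``Δ`` within the nB-nUS plane, toward the
  fan: ``nC = cos Δ · nB + sin Δ · nUS``.
* The rendered fan raster places the apex at pixel
  ``(row 0, col image_width // 2)`` with the central ray pointing down the
  image and the up vector pointing toward increasing column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError

__all__ = [
    "Pose",
    "FanSpec",
    "DeviceFrame",
    "pose_to_frame",
    "frame_axes_to_pose",
    "fan_sample_points",
    "fan_pixel_table",
]

# Canonical body-frame axes (identity pose).
_TIP_AXIS = np.array([0.0, 0.0, 1.0])  # nB
_PROBE_AXIS = np.array([1.0, 0.0, 0.0])  # nUS
_EULER_SEQ = "ZYX"


def _wrap_angle(angle: float) -> float:
    """Normalize an angle in degrees to the half-open interval (-180, 180]."""
    a = math.fmod(float(angle), 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class Pose:
    """6-DOF device state: intrinsic Z-Y-X Euler angles (deg) + position (mm)."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.tx, self.ty, self.tz)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"pose parameters must be finite, got {vals}")
        object.__setattr__(self, "a", _wrap_angle(self.a))
        object.__setattr__(self, "b", _wrap_angle(self.b))
        object.__setattr__(self, "c", _wrap_angle(self.c))

    @property
    def position(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    def rotation(self) -> Rotation:
        return Rotation.from_euler(_EULER_SEQ, [self.a, self.b, self.c], degrees=True)

    def with_position(self, position: np.ndarray) -> "Pose":
        x, y, z = np.asarray(position, dtype=float)
        return replace(self, tx=float(x), ty=float(y), tz=float(z))

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c,
                "tx": self.tx, "ty": self.ty, "tz": self.tz}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(**{k: float(d[k]) for k in ("a", "b", "c", "tx", "ty", "tz")})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Pose":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FanSpec:
    """Scan-geometry constants of the EBUS device and its rendered raster.

    Defaults follow the Olympus BF-UC180F convex-probe EBUS bronchoscope:
    60-degree fan sweep with 40 mm depth range, camera axis offset 20 degrees
    from the tip axis, probe-plane origin 6 mm from the tip start, rendered
    on a 300x300 raster.
    """

    sweep: float = 60.0            # fan angular sweep, degrees
    range: float = 40.0            # fan depth, mm
    camera_offset: float = 20.0    # Δ, degrees
    probe_offset: float = 6.0      # ||sB - sUS||, mm
    image_width: int = 300
    image_height: int = 300
    pixel_spacing: float | None = None  # mm/pixel; None -> range / image_height

    def __post_init__(self) -> None:
        if not (0.0 < self.sweep < 180.0):
            raise InvalidInputError(f"sweep must be in (0, 180), got {self.sweep}")
        if self.range <= 0:
            raise InvalidInputError(f"range must be > 0, got {self.range}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise InvalidInputError("image dimensions must be positive")
        if self.pixel_spacing is not None and self.pixel_spacing <= 0:
            raise InvalidInputError("pixel_spacing must be positive")

    @property
    def spacing(self) -> float:
        """Effective pixel spacing in mm/pixel (range fills the image height)."""
        if self.pixel_spacing is not None:
            return self.pixel_spacing
        return self.range / self.image_height

    @property
    def apex_pixel(self) -> tuple[int, int]:
        """(row, col) of the fan apex in the rendered raster."""
        return (0, self.image_width // 2)

    @classmethod
    def from_dict(cls, d: dict) -> "FanSpec":
        return cls(**d)


@dataclass(frozen=True)
class DeviceFrame:
    """Derived tip geometry at a pose: all vectors unit, world coordinates."""

    s_b: np.ndarray = field(repr=False)   # tip start point, mm
    n_b: np.ndarray = field(repr=False)   # unit tip axis
    n_c: np.ndarray = field(repr=False)   # unit camera axis
    s_us: np.ndarray = field(repr=False)  # probe-plane origin, mm
    n_us: np.ndarray = field(repr=False)  # unit probe axis
    up: np.ndarray = field(repr=False)    # unit in-plane vector spanning the fan


def pose_to_frame(pose: Pose, spec: FanSpec | None = None) -> DeviceFrame:
    """Convert a 6-DOF pose into the full EBUS-bronchoscope tip geometry.

    The rotation of ``pose`` is applied to the canonical body frame
    (tip +z, probe +x); the camera axis is tilted by ``spec.camera_offset``
    degrees from the tip axis within the tip-probe plane, toward the fan,
    and the probe-plane origin sits ``spec.probe_offset`` mm along the tip
    axis from the tip start point.
    """
    if spec is None:
        spec = FanSpec()
    rot = pose.rotation()
    n_b = rot.apply(_TIP_AXIS)
    n_us = rot.apply(_PROBE_AXIS)
    delta = math.radians(spec.camera_offset)
    n_c = math.cos(delta) * n_b + math.sin(delta) * n_us
    s_b = pose.position
    s_us = s_b + spec.probe_offset * n_b
    up = n_b  # fan plane contains the scope axis; see module docstring
    return DeviceFrame(s_b=s_b, n_b=n_b, n_c=n_c, s_us=s_us, n_us=n_us, up=up)


def frame_axes_to_pose(n_b: np.ndarray, n_us: np.ndarray,
                       s_b: np.ndarray) -> Pose:
    """Build the pose whose device frame has the given tip/probe axes.

    Inverse of :func:`pose_to_frame` on the axes: the rotation taking the
    canonical body frame onto ``(n_us, n_b x n_us, n_b)`` is decomposed
    into intrinsic Z-Y-X Euler angles.  ``n_us`` is re-orthogonalized
    against ``n_b`` so slightly inconsistent inputs are tolerated.
    """
    n_b = np.asarray(n_b, dtype=float)
    n_us = np.asarray(n_us, dtype=float)
    nb = n_b / np.linalg.norm(n_b)
    nus = n_us - (n_us @ nb) * nb
    norm = np.linalg.norm(nus)
    if norm < 1e-12:
        raise InvalidInputError("probe axis parallel to tip axis")
    nus /= norm
    mat = np.column_stack([nus, np.cross(nb, nus), nb])
    a, b, c = Rotation.from_matrix(mat).as_euler(_EULER_SEQ, degrees=True)
    x, y, z = np.asarray(s_b, dtype=float)
    return Pose(a=a, b=b, c=c, tx=x, ty=y, tz=z)


def fan_pixel_table(spec: FanSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polar layout of the fan raster, independent of any pose.

    Returns ``(in_fan, radius_mm, offsets_mm)`` where ``in_fan`` is an
    (H, W) boolean mask of pixels inside the fan sector, ``radius_mm`` the
    (H, W) radial distance of each pixel centre from the apex, and
    ``offsets_mm`` an (H, W, 2) array of in-plane displacements
    (along ``n_us``, along ``up``) from the probe-plane origin.

    A pixel is in the fan iff its radius is at most ``spec.range`` and its
    polar angle about the central (down-image) ray is within half the sweep.
    """
    h, w = spec.image_height, spec.image_width
    apex_r, apex_c = spec.apex_pixel
    ps = spec.spacing
    rows = (np.arange(h) - apex_r)[:, None] * ps   # along n_us (down-image), mm
    cols = (np.arange(w) - apex_c)[None, :] * ps   # along up (rightward), mm
    down = np.broadcast_to(rows, (h, w))
    side = np.broadcast_to(cols, (h, w))
    radius = np.hypot(down, side)
    theta = np.degrees(np.arctan2(side, down))     # 0 on the central ray
    in_fan = (radius <= spec.range) & (np.abs(theta) <= spec.sweep / 2.0)
    offsets = np.stack([down, side], axis=-1)
    return in_fan, radius, offsets


def fan_sample_points(frame: DeviceFrame,
                      spec: FanSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map every rendered-view pixel to its 3D world point on the scan plane.

    Returns ``(points, in_fan)`` where ``points`` is (H, W, 3) world mm
    (defined for all pixels; the plane extends beyond the fan) and
    ``in_fan`` flags the pixels inside the fan sector.  The apex pixel maps
    exactly to the probe-plane origin ``s_us``.
    """
    in_fan, _, offsets = fan_pixel_table(spec)
    points = (frame.s_us[None, None, :]
              + offsets[..., 0:1] * frame.n_us[None, None, :]
              + offsets[..., 1:2] * frame.up[None, None, :])
    return points, in_fan
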