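"""Synthetic chest phantoms for end-to-end testing without patient data.

:func:`generate_phantom` builds an axis-aligned CT volume containing an
air-filled airway tube (straight, or a two-branch Y) with a bright wall,
an adjacent ellipsoidal lymph node, and a vessel cylinder, all at
realistic HU levels (air -1000, wall 125, soft tissue 40, node 30, vessel
60) plus Gaussian noise.  The node is deliberately low-contrast against
soft tissue, mirroring the clinical situation in which the Dice shape
term — not raw intensity — must drive registration.  Alongside the volume
it returns the matching label volume, the endoluminal surface voxels, the
centerline polyline, and ground-truth probe poses that sit on the wall
with the viewing axis aimed at the node centroid.

:func:`simulate_ebus_frame` converts the clean virtual rendering at a pose
into an ultrasound-looking frame: intensity inversion (node hypoechoic),
exponential depth attenuation, mean-one multiplicative Rayleigh speckle,
and Gaussian blur.  The speckle is mean-preserving in the linear domain so
ensemble averages converge to the clean image; it is a qualitative test
stand-in, not an acoustic simulation.  The frame's ROI mask is copied from
the clean rendering, emulating an external EBUS-frame segmenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cost import EBUSFrame, FanImageGeometry
from .errors import InvalidInputError, InvalidSpecError
from .geometry import FanSpec, Pose, frame_axes_to_pose, pose_to_frame
from .renderer import (CTVolume, LabelVolume, TARGET_LABEL, VESSEL_LABEL,
                       render_view)
from .wall import AirwaySurface, WallConfig, first_wall_point, surface_from_mask

__all__ = [
    "PhantomSpec",
    "EBUSNoiseSpec",
    "Phantom",
    "generate_phantom",
    "simulate_ebus_frame",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU levels of the synthetic phantom.

    Default volume: 160 x 160 x 200 voxels at 0.7 mm isotropic (112 x 112
    x 140 mm), a straight airway tube along z through the volume centre
    with 8 mm inner radius and 2 mm wall, a 12 x 16 x 14 mm-axis node
    pressed against the wall at mid-height, and a 4 mm vessel cylinder on
    the opposite side.
    """

    shape: tuple[int, int, int] = (160, 160, 200)
    spacing: float = 0.7                     # mm, isotropic
    branch: bool = False                     # straight tube or two-branch Y
    inner_radius: float = 8.0                # mm, lumen radius
    wall_thickness: float = 2.0              # mm
    node_center: tuple[float, float, float] | None = None  # mm; None -> auto
    node_semi_axes: tuple[float, float, float] = (6.0, 8.0, 7.0)  # mm
    vessel_radius: float = 4.0               # mm
    hu_air: float = -1000.0
    hu_wall: float = 125.0
    hu_soft_tissue: float = 40.0
    hu_node: float = 30.0
    hu_vessel: float = 60.0
    noise_sigma: float = 10.0                # HU, additive Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius <= 0 or self.wall_thickness <= 0:
            raise InvalidSpecError("tube radii must be positive")
        if not (50.0 <= self.hu_wall <= 200.0):
            raise InvalidSpecError(
                f"wall HU must lie in [50, 200], got {self.hu_wall}")


@dataclass(frozen=True)
class EBUSNoiseSpec:
    """Degradation model of the pseudo-EBUS simulator."""

    speckle_weight: float = 0.5       # 0 disables; blends mean-one Rayleigh
    attenuation: float = 0.015        # per mm of depth
    blur_sigma: float = 1.0           # px
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.speckle_weight, self.attenuation, self.blur_sigma) < 0:
            raise InvalidInputError("noise parameters must be >= 0")


@dataclass
class Phantom:
    """Bundle returned by :func:`generate_phantom`."""

    ct: CTVolume
    labels: LabelVolume
    surface: AirwaySurface
    centerline: np.ndarray = field(repr=False)
    gt_poses: list[Pose] = field(default_factory=list)
    spec: PhantomSpec = field(default_factory=PhantomSpec)

    @property
    def node_center(self) -> np.ndarray:
        idx = np.argwhere(self.labels.labels == TARGET_LABEL)
        return self.ct.index_to_world(idx).mean(axis=0)


def _default_node_center(spec: PhantomSpec) -> np.ndarray:
    extent = np.asarray(spec.shape) * spec.spacing
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    cz = extent[2] / 2.0
    # pressed against the outer wall along +x
    x = cx + spec.inner_radius + spec.wall_thickness + spec.node_semi_axes[0]
    return np.array([x, cy, cz])


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the synthetic CT phantom, labels, surface, centerline, poses.

    Deterministic for a given ``spec`` (the RNG is seeded from
    ``spec.seed``).  Raises :class:`InvalidSpecError` if the node
    intersects the airway lumen.
    """
    if spec is None:
        spec = PhantomSpec()
    nx, ny, nz = spec.shape
    sp = spec.spacing
    extent = np.array([nx, ny, nz]) * sp
    cx, cy = extent[0] / 2.0, extent[1] / 2.0

    xs = (np.arange(nx) * sp)[:, None, None]
    ys = (np.arange(ny) * sp)[None, :, None]
    zs = (np.arange(nz) * sp)[None, None, :]

    r_out = spec.inner_radius + spec.wall_thickness
    if spec.branch:
        # trunk along z up to 60% height, then two branches splayed in x
        z_split = 0.6 * extent[2]
        lumen = np.zeros(spec.shape, dtype=bool)
        wallm = np.zeros(spec.shape, dtype=bool)
        cl_pts, cl_branch = [], []
        # trunk
        rad2 = (xs - cx) ** 2 + (ys - cy) ** 2
        trunk = zs <= z_split
        lumen |= (rad2 <= spec.inner_radius ** 2) & trunk
        wallm |= (rad2 <= r_out ** 2) & trunk
        for z in np.arange(0, z_split, sp):
            cl_pts.append([cx, cy, z])
            cl_branch.append(0)
        # branches at ±30 degrees in the x-z plane
        for b, sign in ((1, 1.0), (2, -1.0)):
            ang = math.radians(30.0)
            d = np.array([sign * math.sin(ang), 0.0, math.cos(ang)])
            o = np.array([cx, cy, z_split])
            px = xs - o[0]
            py = ys - o[1]
            pz = zs - o[2]
            t = px * d[0] + py * d[1] + pz * d[2]
            d2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 \
                + (pz - t * d[2]) ** 2
            seg = (t >= 0) & (t <= extent[2] - z_split)
            lumen |= (d2 <= spec.inner_radius ** 2) & seg
            wallm |= (d2 <= r_out ** 2) & seg
            for tt in np.arange(0, (extent[2] - z_split) / d[2], sp):
                cl_pts.append(list(o + tt * d))
                cl_branch.append(b)
        centerline = np.asarray(cl_pts)
        cl_branches = np.asarray(cl_branch)
    else:
        rad2 = (xs - cx) ** 2 + (ys - cy) ** 2
        lumen = np.broadcast_to(rad2 <= spec.inner_radius ** 2,
                                spec.shape).copy()
        wallm = np.broadcast_to(rad2 <= r_out ** 2, spec.shape).copy()
        centerline = np.column_stack([
            np.full(nz, cx), np.full(nz, cy), np.arange(nz) * sp])
        cl_branches = np.zeros(nz, dtype=int)
    wallm &= ~lumen

    node_c = np.asarray(spec.node_center) if spec.node_center is not None \
        else _default_node_center(spec)
    na, nb_, nc = spec.node_semi_axes
    node = (((xs - node_c[0]) / na) ** 2 + ((ys - node_c[1]) / nb_) ** 2
            + ((zs - node_c[2]) / nc) ** 2) <= 1.0
    if (node & lumen).any():
        raise InvalidSpecError("node ellipsoid intersects the airway lumen")

    vx = cx - (r_out + 3.0 * spec.vessel_radius)
    vessel = (xs - vx) ** 2 + (ys - cy) ** 2 <= spec.vessel_radius ** 2
    vessel = np.broadcast_to(vessel, spec.shape).copy()
    vessel &= ~lumen & ~wallm

    hu = np.full(spec.shape, spec.hu_soft_tissue, dtype=np.float32)
    hu[vessel] = spec.hu_vessel
    hu[node & ~wallm] = spec.hu_node
    hu[wallm] = spec.hu_wall
    hu[lumen] = spec.hu_air
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma,
                             size=spec.shape).astype(np.float32)
        hu[lumen] = np.minimum(hu[lumen], -900.0)  # keep lumen sub-threshold

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[vessel] = VESSEL_LABEL
    labels[node & ~lumen] = TARGET_LABEL

    spacing = (sp, sp, sp)
    ct = CTVolume(hu=hu, spacing=spacing)
    lab = LabelVolume(labels=labels, spacing=spacing)
    surface = surface_from_mask(lumen, ct, centerline, cl_branches)
    gt_poses = _ground_truth_poses(ct, surface, centerline, node_c)
    return Phantom(ct=ct, labels=lab, surface=surface, centerline=centerline,
                   gt_poses=gt_poses, spec=spec)


def _ground_truth_poses(ct: CTVolume, surface: AirwaySurface,
                        centerline: np.ndarray, node_c: np.ndarray,
                        n_poses: int = 12,
                        fan: FanSpec | None = None) -> list[Pose]:
    """Wall poses whose probe axis points at the node centroid.

    From centerline points near the node's height, the ray toward the node
    centroid is marched to the first wall voxel; the probe origin is that
    voxel's centre (so wall adjustment is a fixed point of the pose), the
    probe axis is the ray direction, and the tip axis is the local airway
    direction made orthogonal to the probe axis.
    """
    if fan is None:
        fan = FanSpec()
    wall_cfg = WallConfig()
    d_axial = np.abs(centerline[:, 2] - node_c[2])
    order = np.argsort(d_axial)
    poses: list[Pose] = []
    for i in order:
        if len(poses) >= n_poses:
            break
        cl = centerline[i]
        d = node_c - cl
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        d = d / norm
        try:
            s_us = first_wall_point(ct, cl, d, wall_cfg)
        except Exception:
            continue
        # local airway direction, orthogonalized against the probe axis
        j = min(i + 1, len(centerline) - 1)
        k = max(i - 1, 0)
        axis = centerline[j] - centerline[k]
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
        n_b = axis - (axis @ d) * d
        if np.linalg.norm(n_b) < 1e-9:
            continue
        n_b = n_b / np.linalg.norm(n_b)
        # probe axis must point at the node from s_us (same ray, so it does)
        pose = frame_axes_to_pose(n_b=n_b, n_us=d,
                                  s_b=s_us - fan.probe_offset * n_b)
        # re-anchor the position through the pose's own (Euler-round-tripped)
        # tip axis so wall adjustment is a bitwise fixed point of the pose
        pose = pose.with_position(
            s_us - fan.probe_offset * pose_to_frame(pose, fan).n_b)
        poses.append(pose)
    return poses


def simulate_ebus_frame(ct: CTVolume, labels: LabelVolume, pose: Pose,
                        fan: FanSpec | None = None,
                        noise: EBUSNoiseSpec | None = None,
                        remap: str = "ultrasound") -> EBUSFrame:
    """Render a pseudo-EBUS frame at a pose (test stand-in for a real frame).

    ``remap='ultrasound'`` inverts intensities (the node becomes
    hypoechoic) before applying depth attenuation, mean-one multiplicative
    Rayleigh speckle, and Gaussian blur; ``remap='identity'`` keeps the
    rendered gray values (with zero noise the frame then equals the clean
    rendering exactly).  The ROI mask is the clean projected ROI.
    Deterministic per ``noise.seed``.
    """
    if fan is None:
        fan = FanSpec()
    if noise is None:
        noise = EBUSNoiseSpec()
    if remap not in ("ultrasound", "identity"):
        raise InvalidInputError(f"unknown remap {remap!r}")
    view = render_view(ct, labels, pose, fan)
    img = view.image.astype(float)
    if remap == "ultrasound":
        img = 255.0 - img
    if noise.attenuation > 0:
        _, radius, _ = _fan_radius(fan)
        img = img * np.exp(-noise.attenuation * radius)
    if noise.speckle_weight > 0:
        rng = np.random.default_rng(noise.seed)
        sigma = math.sqrt(2.0 / math.pi)  # Rayleigh(sigma) has mean 1
        speckle = rng.rayleigh(sigma, size=img.shape)
        img = img * (1.0 - noise.speckle_weight
                     + noise.speckle_weight * speckle)
    if noise.blur_sigma > 0:
        img = gaussian_filter(img, noise.blur_sigma)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img[~view.fan_mask] = 0
    return EBUSFrame(image=img, roi_mask=view.roi_mask.copy(),
                     fan_geometry=FanImageGeometry.from_fan_spec(fan))


def _fan_radius(fan: FanSpec) -> tuple[np.ndarray, np.ndarray, None]:
    """Per-pixel depth (mm) from the fan apex, for attenuation."""
    geom = FanImageGeometry.from_fan_spec(fan)
    radius_px, _ = geom.polar((fan.image_height, fan.image_width))
    return None, radius_px * fan.spacing, None
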