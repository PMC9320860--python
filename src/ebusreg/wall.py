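"""Airway-wall constraint for candidate probe poses.

A convex-probe EBUS view only exists when the probe is pushed against the
airway wall, so every candidate pose of the registration search must sit
on the endoluminal surface.  This module provides the three pieces of
that constraint:

* ray-marching along the probe viewing axis to the first voxel brighter
  than a conservative wall threshold (-600 HU; air is about -1000 HU and
  airway walls 50-200 HU);
* projection of an arbitrary candidate point onto the wall through an
  exact nearest-neighbour search over the surface voxels, with a
  dot-product test that detects projections landing on the wrong airway
  branch and a centerline-based fallback that re-shoots the ray from the
  correct branch;
* construction of the initial 7-vertex simplex (the unperturbed pose plus
  one vertex per pose parameter), every vertex wall-adjusted.

Wall adjustment acts on the probe-plane origin ``s_us`` (the physical
point that must touch the wall); the pose position ``s_b`` is then
recomputed as ``s_us - probe_offset * n_b``.  Angular components of a
perturbed vertex are kept as generated.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .errors import (InvalidInputError, NoWallFoundError,
                     SimplexConstructionError)
from .geometry import FanSpec, Pose, pose_to_frame
from .renderer import CTVolume

__all__ = [
    "AirwaySurface",
    "WallConfig",
    "first_wall_point",
    "project_vertex",
    "wall_adjust_pose",
    "initial_simplex",
    "surface_from_mask",
    "DEFAULT_INCREMENTS",
]

# Default simplex increments: one per pose parameter (da, db, dc in degrees,
# dtx, dty, dtz in mm) — the step sizes of the sensitivity protocol.
DEFAULT_INCREMENTS = (25.0, 25.0, 25.0, 2.5, 2.5, 2.5)


@dataclass
class AirwaySurface:
    """Endoluminal surface voxels plus branch centerlines, world mm.

    ``surface_points`` is (N, 3); ``centerline_points`` is (M, 3) with a
    parallel ``centerline_branches`` array of branch ids.  Nearest
    neighbour queries are exact (k-d tree, ties to the lowest index).
    """

    surface_points: np.ndarray
    centerline_points: np.ndarray
    centerline_branches: np.ndarray | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.surface_points = np.atleast_2d(
            np.asarray(self.surface_points, dtype=float))
        self.centerline_points = np.atleast_2d(
            np.asarray(self.centerline_points, dtype=float))
        if self.surface_points.size == 0:
            raise InvalidInputError("surface has no points")
        if self.centerline_branches is None:
            self.centerline_branches = np.zeros(
                len(self.centerline_points), dtype=int)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.surface_points)
        return self._tree

    def nearest_surface_point(self, point: np.ndarray) -> np.ndarray:
        _, i = self.tree.query(np.asarray(point, dtype=float))
        return self.surface_points[int(i)]

    def nearest_centerline_point(self, point: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(self.centerline_points - np.asarray(point), axis=1)
        return self.centerline_points[int(np.argmin(d))]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, surface_path: str | Path,
               centerline_path: str | Path | None = None) -> None:
        np.savetxt(surface_path, self.surface_points, fmt="%.6f",
                   delimiter=",", header="x,y,z", comments="")
        if centerline_path is not None:
            with open(centerline_path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["branch_id", "x", "y", "z"])
                for b, (x, y, z) in zip(self.centerline_branches,
                                        self.centerline_points):
                    w.writerow([int(b), f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])

    @classmethod
    def from_csv(cls, surface_path: str | Path,
                 centerline_path: str | Path) -> "AirwaySurface":
        pts = np.loadtxt(surface_path, delimiter=",", skiprows=1)
        rows = np.loadtxt(centerline_path, delimiter=",", skiprows=1)
        rows = np.atleast_2d(rows)
        return cls(surface_points=pts, centerline_points=rows[:, 1:4],
                   centerline_branches=rows[:, 0].astype(int))


@dataclass(frozen=True)
class WallConfig:
    """Wall-search settings."""

    hu_threshold: float = -600.0  # conservative airway-wall HU threshold
    accept_radius: float = 1.0    # mm: near-surface acceptance band
    ray_step: float | None = None  # mm; None -> min voxel spacing / 2

    def __post_init__(self) -> None:
        if self.accept_radius <= 0:
            raise InvalidInputError("accept_radius must be > 0")
        if self.ray_step is not None and self.ray_step <= 0:
            raise InvalidInputError("ray_step must be > 0")

    def step_for(self, ct: CTVolume) -> float:
        return self.ray_step if self.ray_step is not None \
            else min(ct.spacing) / 2.0


def surface_from_mask(lumen_mask: np.ndarray, ct: CTVolume,
                      centerline_points: np.ndarray,
                      centerline_branches: np.ndarray | None = None,
                      ) -> AirwaySurface:
    """Extract the one-voxel wall layer adjacent to an airway lumen mask.

    Surface voxels are the non-lumen voxels 6-adjacent to the lumen — the
    innermost wall layer, whose HU exceeds the wall threshold on any
    realistic volume.
    """
    lumen = np.asarray(lumen_mask, dtype=bool)
    if lumen.shape != ct.shape:
        raise InvalidInputError("lumen mask shape != CT shape")
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True
    shell = binary_dilation(lumen, structure=struct) & ~lumen
    idx = np.argwhere(shell)
    pts = ct.index_to_world(idx)
    return AirwaySurface(surface_points=pts,
                         centerline_points=centerline_points,
                         centerline_branches=centerline_branches)


def first_wall_point(ct: CTVolume, origin: np.ndarray, direction: np.ndarray,
                     cfg: WallConfig | None = None) -> np.ndarray:
    """Center of the first voxel along a ray whose HU exceeds the threshold.

    Marches from ``origin`` along unit ``direction`` in sub-voxel steps;
    the origin's own voxel is tested first (zero-length march).  Raises
    :class:`NoWallFoundError` if the ray exits the volume below threshold.
    """
    if cfg is None:
        cfg = WallConfig()
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
        raise InvalidInputError("direction must be unit-norm")
    if not ct.contains(origin):
        raise InvalidInputError(f"ray origin {origin} outside volume")
    step = cfg.step_for(ct)
    max_dist = float(np.linalg.norm(
        np.asarray(ct.shape) * np.asarray(ct.spacing)))
    t = 0.0
    while t <= max_dist:
        p = origin + t * direction
        if not ct.contains(p):
            break
        if ct.hu_at_voxel(p) > cfg.hu_threshold:
            return ct.index_to_world(np.array(ct.voxel_index(p)))
        t += step
    raise NoWallFoundError(
        f"ray from {origin} along {direction} never crossed "
        f"{cfg.hu_threshold} HU")


def project_vertex(pv: np.ndarray, pi: np.ndarray, surface: AirwaySurface,
                   ct: CTVolume, cfg: WallConfig | None = None) -> np.ndarray:
    """Project a candidate point onto the airway wall near the reference.

    With ``ps`` the nearest surface voxel to ``pv``:

    1. if ``pv`` itself is above the wall HU threshold and within the
       acceptance radius of ``ps`` (thick-wall tolerance), ``pv`` is
       accepted unchanged;
    2. else if ``(pv - pi) · (pv - ps) > 0``, ``ps`` is on the correct
       branch and is returned;
    3. else ``ps`` came from the wrong branch: the centerline point
       closest to the reference ``pi`` is found and the ray from it toward
       ``pv`` is marched to the first wall voxel, which is returned.
    """
    if cfg is None:
        cfg = WallConfig()
    pv = np.asarray(pv, dtype=float)
    pi = np.asarray(pi, dtype=float)
    ps = surface.nearest_surface_point(pv)
    dist = float(np.linalg.norm(pv - ps))
    if dist < cfg.accept_radius and ct.contains(pv) \
            and ct.hu_at_voxel(pv) > cfg.hu_threshold:
        return pv
    v1 = pv - pi
    v2 = pv - ps
    if float(v1 @ v2) > 0.0:
        return ps
    pl = surface.nearest_centerline_point(pi)
    d = pv - pl
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise NoWallFoundError("candidate coincides with the centerline point")
    return first_wall_point(ct, pl, d / norm, cfg)


def wall_adjust_pose(pose: Pose, ct: CTVolume, fan: FanSpec,
                     cfg: WallConfig | None = None) -> Pose:
    """Push a pose's probe origin onto the wall along its viewing axis.

    The probe origin ``s_us`` is advanced along ``n_us`` to the first wall
    voxel center; the pose position follows (``s_b = s_us' - offset·n_b``).
    """
    frame = pose_to_frame(pose, fan)
    s_us = first_wall_point(ct, frame.s_us, frame.n_us, cfg)
    return pose.with_position(s_us - fan.probe_offset * frame.n_b)


def _project_pose(pose: Pose, reference_s_us: np.ndarray,
                  surface: AirwaySurface, ct: CTVolume, fan: FanSpec,
                  cfg: WallConfig) -> Pose:
    frame = pose_to_frame(pose, fan)
    s_us = project_vertex(frame.s_us, reference_s_us, surface, ct, cfg)
    return pose.with_position(s_us - fan.probe_offset * frame.n_b)


def initial_simplex(pi: Pose,
                    increments: tuple[float, ...] = DEFAULT_INCREMENTS,
                    surface: AirwaySurface | None = None,
                    ct: CTVolume | None = None,
                    fan: FanSpec | None = None,
                    cfg: WallConfig | None = None) -> list[Pose]:
    """Build the 7-pose initial simplex on the airway wall.

    Vertex 0 is ``pi`` with its probe origin wall-adjusted along the
    viewing axis; vertices 1-6 each perturb exactly one pose parameter
    (order a, b, c, tx, ty, tz) by its increment and are then
    wall-projected.  All-zero increments yield a degenerate simplex and a
    warning.
    """
    if fan is None:
        fan = FanSpec()
    if cfg is None:
        cfg = WallConfig()
    if ct is None or surface is None:
        raise InvalidInputError("initial_simplex needs a CT volume and surface")
    if len(increments) != 6:
        raise InvalidInputError("need six increments (da, db, dc, dtx, dty, dtz)")
    if all(v == 0 for v in increments):
        warnings.warn("all simplex increments are zero: degenerate simplex",
                      stacklevel=2)
    try:
        base = wall_adjust_pose(pi, ct, fan, cfg)
    except NoWallFoundError as exc:
        raise SimplexConstructionError(
            f"initial pose does not project to the wall: {exc}") from exc
    ref_s_us = pose_to_frame(base, fan).s_us
    vertices = [base]
    params = ("a", "b", "c", "tx", "ty", "tz")
    for name, delta in zip(params, increments):
        d = dict(zip(params, (base.a, base.b, base.c, base.tx, base.ty,
                              base.tz)))
        d[name] += delta
        try:
            vertices.append(_project_pose(Pose(**d), ref_s_us, surface, ct,
                                          fan, cfg))
        except NoWallFoundError as exc:
            raise SimplexConstructionError(
                f"vertex perturbing {name} unprojectable: {exc}") from exc
    return vertices
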