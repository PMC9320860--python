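"""Wall-constrained simplex registration of virtual to real EBUS views.

The registration solves

    po = argmin_{p in N_pi} C(ICTp, IUS)

by a Nelder-Mead simplex search over the 6-DOF pose, with every candidate
pose projected onto the airway wall before its cost is evaluated (the
probe must touch the wall to image).  The full algorithm:

1.  Wall-adjust the initial pose ``pi`` and build a 7-vertex simplex on
    the wall (one vertex per perturbed pose parameter).
2.  Iterate the simplex (reflect / expand / contract / shrink; every new
    pose wall-projected before evaluation) until the wall voxel containing
    the best pose is unchanged for ``T`` consecutive iterations.
3.  Restart steps 1-2 from ``pi := po`` until the voxel containing ``po``
    no longer changes between restarts.
4.  Return ``po`` and the virtual view rendered there.

Inside the simplex the three Euler angles are scaled to millimetre
equivalents through a characteristic length equal to the probe range, so
a single simplex geometry is meaningful across the heterogeneous
parameters.  The optimizer itself uses no random numbers: identical
inputs give bit-identical results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cost import (CostConfig, EBUSFrame, TrapezoidRegion, bounding_trapezoid,
                   total_cost)
from .errors import NoWallFoundError
from .geometry import FanSpec, Pose, pose_to_frame
from .renderer import CTVolume, DEFAULT_HU_WINDOW, LabelVolume, render_view
from .wall import (AirwaySurface, DEFAULT_INCREMENTS, WallConfig,
                   _project_pose, initial_simplex)

__all__ = ["RegistrationConfig", "SimplexState", "RegistrationResult",
           "register", "simplex_step"]

logger = logging.getLogger(__name__)

_PARAMS = ("a", "b", "c", "tx", "ty", "tz")


@dataclass(frozen=True)
class RegistrationConfig:
    """Tunables of the registration search.

    ``T`` is the number of consecutive simplex iterations the best pose's
    wall voxel must stay unchanged before the inner loop stops (default
    15, the value at which further gains are marginal relative to run
    time).  Reflection/expansion/contraction/shrink coefficients default
    to the standard Nelder-Mead values.
    """

    T: int = 15
    max_inner_iterations: int = 500
    max_outer_restarts: int = 20
    increments: tuple[float, ...] = DEFAULT_INCREMENTS
    fan: FanSpec = field(default_factory=FanSpec)
    wall: WallConfig = field(default_factory=WallConfig)
    cost: CostConfig = field(default_factory=CostConfig)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    alpha: float = 1.0   # reflection
    gamma: float = 2.0   # expansion
    rho: float = 0.5     # contraction
    sigma: float = 0.5   # shrink
    angle_scale: float | None = None  # mm per degree; None -> range * pi/180
    allow_degenerate: bool = True  # treat all-constant regions as CN = -1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def deg_to_mm(self) -> float:
        if self.angle_scale is not None:
            return self.angle_scale
        return self.fan.range * math.pi / 180.0


@dataclass
class SimplexState:
    """Seven wall-projected poses and their costs."""

    vertices: list[Pose]
    costs: list[float]

    def __post_init__(self) -> None:
        if len(self.vertices) != len(self.costs):
            raise ValueError("vertices and costs length mismatch")
        if not all(math.isfinite(c) for c in self.costs):
            raise ValueError("costs must be finite")

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.costs))  # argmin ties -> lowest index

    @property
    def best(self) -> tuple[Pose, float]:
        i = self.best_index
        return self.vertices[i], self.costs[i]


@dataclass
class RegistrationResult:
    """Optimal pose with its rendered view and search diagnostics."""

    po: Pose
    final_view: object
    final_cost: float
    components: dict
    cost_trace: list[float]
    inner_iterations: int
    outer_restarts: int
    status: str  # 'converged' | 'max_inner' | 'max_outer'


def _pose_to_vec(pose: Pose, scale: float) -> np.ndarray:
    return np.array([pose.a * scale, pose.b * scale, pose.c * scale,
                     pose.tx, pose.ty, pose.tz])


def _vec_to_pose(vec: np.ndarray, scale: float) -> Pose:
    return Pose(a=vec[0] / scale, b=vec[1] / scale, c=vec[2] / scale,
                tx=vec[3], ty=vec[4], tz=vec[5])


def simplex_step(state: SimplexState, evaluate, project,
                 cfg: RegistrationConfig | None = None) -> SimplexState:
    """One Nelder-Mead iteration with wall projection of every new pose.

    ``evaluate``: pose -> cost; ``project``: pose -> wall-projected pose.
    A projection failure during reflection/expansion/contraction rejects
    that move and falls through to a shrink; a failure during shrink keeps
    the affected vertex unchanged.  The best vertex never worsens.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    scale = cfg.deg_to_mm
    order = np.argsort(np.asarray(state.costs), kind="stable")
    vertices = [state.vertices[i] for i in order]
    costs = [state.costs[i] for i in order]
    if all(v == vertices[0] for v in vertices[1:]):
        logger.debug("degenerate simplex: all vertices equal")
        return SimplexState(vertices=vertices, costs=costs)
    vecs = np.stack([_pose_to_vec(v, scale) for v in vertices])
    centroid = vecs[:-1].mean(axis=0)
    worst = vecs[-1]

    def attempt(vec: np.ndarray) -> tuple[Pose, float] | None:
        try:
            pose = project(_vec_to_pose(vec, scale))
        except NoWallFoundError:
            return None
        return pose, evaluate(pose)

    refl = attempt(centroid + cfg.alpha * (centroid - worst))
    if refl is not None:
        pose_r, cost_r = refl
        if cost_r < costs[0]:
            exp = attempt(centroid + cfg.gamma * (centroid - worst))
            if exp is not None and exp[1] < cost_r:
                vertices[-1], costs[-1] = exp
            else:
                vertices[-1], costs[-1] = pose_r, cost_r
            return SimplexState(vertices=vertices, costs=costs)
        if cost_r < costs[-2]:
            vertices[-1], costs[-1] = pose_r, cost_r
            return SimplexState(vertices=vertices, costs=costs)
        if cost_r < costs[-1]:  # outside contraction
            con = attempt(centroid + cfg.rho * (centroid - worst))
            if con is not None and con[1] <= cost_r:
                vertices[-1], costs[-1] = con
                return SimplexState(vertices=vertices, costs=costs)
        else:  # inside contraction
            con = attempt(centroid - cfg.rho * (centroid - worst))
            if con is not None and con[1] < costs[-1]:
                vertices[-1], costs[-1] = con
                return SimplexState(vertices=vertices, costs=costs)
    # shrink toward the best vertex
    best_vec = vecs[0]
    for i in range(1, len(vertices)):
        shrunk = attempt(best_vec + cfg.sigma * (vecs[i] - best_vec))
        if shrunk is not None:
            vertices[i], costs[i] = shrunk
    return SimplexState(vertices=vertices, costs=costs)


def register(ct: CTVolume, labels: LabelVolume, surface: AirwaySurface,
             frame: EBUSFrame, pi: Pose,
             cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Full wall-constrained CT-EBUS registration from an initial pose.

    Requires a nonempty ROI mask in ``frame`` (EBUS-frame segmentation is
    an input).  Returns the optimal pose, its rendered virtual view, the
    cost components, and the (non-increasing) best-cost trace.  On hitting
    the iteration caps the best pose found so far is returned with the
    corresponding status flag.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    region: TrapezoidRegion = bounding_trapezoid(frame)
    cache: dict[tuple, tuple[float, dict]] = {}

    def evaluate_full(pose: Pose) -> tuple[float, dict]:
        key = (round(pose.a, 9), round(pose.b, 9), round(pose.c, 9),
               round(pose.tx, 9), round(pose.ty, 9), round(pose.tz, 9))
        hit = cache.get(key)
        if hit is None:
            view = render_view(ct, labels, pose, cfg.fan,
                               window=cfg.hu_window)
            comp = total_cost(view, frame, cfg.cost, region=region,
                              allow_degenerate=cfg.allow_degenerate)
            hit = (comp["C"], comp)
            cache[key] = hit
        return hit

    def evaluate(pose: Pose) -> float:
        return evaluate_full(pose)[0]

    trace: list[float] = []
    best_pose: Pose | None = None
    best_cost = math.inf
    inner_total = 0
    status = "max_outer"
    pi_cur = pi
    prev_voxel = None

    for restart in range(cfg.max_outer_restarts):
        vertices = initial_simplex(pi_cur, cfg.increments, surface, ct,
                                   cfg.fan, cfg.wall)
        ref_s_us = pose_to_frame(vertices[0], cfg.fan).s_us

        def project(pose: Pose) -> Pose:
            return _project_pose(pose, ref_s_us, surface, ct, cfg.fan,
                                 cfg.wall)

        state = SimplexState(vertices=vertices,
                             costs=[evaluate(v) for v in vertices])
        if state.best[1] < best_cost:
            best_pose, best_cost = state.best
        trace.append(best_cost)

        stable = 0
        voxel = ct.voxel_index(state.best[0].position)
        inner_status = "max_inner"
        for _ in range(cfg.max_inner_iterations):
            state = simplex_step(state, evaluate, project, cfg)
            inner_total += 1
            if state.best[1] < best_cost:
                best_pose, best_cost = state.best
            trace.append(best_cost)
            new_voxel = ct.voxel_index(state.best[0].position)
            stable = stable + 1 if new_voxel == voxel else 0
            voxel = new_voxel
            if stable >= cfg.T:
                inner_status = "converged"
                break
        po, po_cost = state.best
        logger.info("restart %d: best cost %.4f at voxel %s", restart,
                    po_cost, voxel)
        po_voxel = ct.voxel_index(po.position)
        if prev_voxel is not None and po_voxel == prev_voxel:
            status = "converged" if inner_status == "converged" else "max_inner"
            break
        prev_voxel = po_voxel
        pi_cur = po

    final_cost, components = evaluate_full(best_pose)
    final_view = render_view(ct, labels, best_pose, cfg.fan,
                             window=cfg.hu_window)
    return RegistrationResult(po=best_pose, final_view=final_view,
                              final_cost=final_cost, components=components,
                              cost_trace=trace,
                              inner_iterations=inner_total,
                              outer_restarts=restart + 1, status=status)
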