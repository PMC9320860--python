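"""Registration cost between a virtual EBUS view and a real EBUS frame.

The cost combines raw intensity information with ROI shape knowledge:

    C = CN - CD,            -2 <= C <= 1

where CN is a normalized-mutual-information cost

    CN = 1 - (h(a) + h(b)) / h(a, b)

built from marginal and joint Shannon entropies of the two images'
gray-level histograms (M = 256 levels, natural log — the entropy ratio is
base-invariant), and CD is the Dice overlap of the two ROI masks

    CD = 2 |R1 ∩ R2| / (|R1| + |R2|).

CN is -1 for perfectly correlated (e.g. identical non-constant) images and
approaches 0 in the independence limit; CD is 1 for identical nonempty
masks, 0 for disjoint masks.

EBUS frames are noisy and mostly bland, so the histograms are not taken
over the whole image: they are restricted to the smallest polar box
(radius x angle about the fan apex — an annular sector whose raster
footprint is trapezoid-like) that bounds the segmented ROI of the EBUS
frame and stays inside the fan.  The trapezoid is fixed once per
registration from the EBUS ROI and reused for every candidate virtual
view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateEntropyError, EmptyRegionError, EmptyROIError,
                     InvalidInputError)
from .geometry import FanSpec

__all__ = [
    "FanImageGeometry",
    "EBUSFrame",
    "TrapezoidRegion",
    "CostConfig",
    "bounding_trapezoid",
    "joint_histogram",
    "nmi_cost",
    "dice_index",
    "total_cost",
]

MIN_REGION_PX = 8  # minimum trapezoid side, pixels (degenerate-ROI floor)


@dataclass(frozen=True)
class FanImageGeometry:
    """Fan geometry expressed in image coordinates of a frame raster."""

    apex_row: float
    apex_col: float
    sweep: float      # degrees
    range_px: float   # fan depth in pixels

    @classmethod
    def from_fan_spec(cls, spec: FanSpec) -> "FanImageGeometry":
        r, c = spec.apex_pixel
        return cls(apex_row=float(r), apex_col=float(c), sweep=spec.sweep,
                   range_px=spec.range / spec.spacing)

    def polar(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (radius_px, angle_deg) about the apex; angle 0 is the
        central (down-image) ray, positive toward increasing column."""
        rows = np.arange(shape[0])[:, None] - self.apex_row
        cols = np.arange(shape[1])[None, :] - self.apex_col
        radius = np.hypot(rows, cols)
        theta = np.degrees(np.arctan2(np.broadcast_to(cols, shape),
                                      np.broadcast_to(rows, shape)))
        return radius, theta

    def fan_mask(self, shape: tuple[int, int]) -> np.ndarray:
        radius, theta = self.polar(shape)
        return (radius <= self.range_px) & (np.abs(theta) <= self.sweep / 2)


@dataclass
class EBUSFrame:
    """A (real or simulated) EBUS frame with its segmented target ROI."""

    image: np.ndarray                 # uint8 gray, (H, W)
    roi_mask: np.ndarray              # bool, (H, W)
    fan_geometry: FanImageGeometry

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.image.shape != self.roi_mask.shape:
            raise InvalidInputError("EBUS image and ROI mask shapes differ")


@dataclass
class TrapezoidRegion:
    """Annular-sector histogram region in fan polar coordinates."""

    r_lo: float
    r_hi: float
    theta_lo: float
    theta_hi: float
    mask: np.ndarray = field(repr=False)  # bool raster over the view

    def __post_init__(self) -> None:
        if not self.r_lo < self.r_hi:
            raise InvalidInputError("trapezoid needs r_lo < r_hi")
        if not self.theta_lo < self.theta_hi:
            raise InvalidInputError("trapezoid needs theta_lo < theta_hi")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class CostConfig:
    """Histogram settings for the NMI term."""

    gray_levels: int = 256
    histogram_epsilon: float = 0.0  # optional additive smoothing per bin

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise InvalidInputError("need at least 2 gray levels")
        if self.histogram_epsilon < 0:
            raise InvalidInputError("histogram_epsilon must be >= 0")


def bounding_trapezoid(frame: EBUSFrame,
                       min_size_px: int = MIN_REGION_PX) -> TrapezoidRegion:
    """Smallest polar box about the fan apex bounding the frame's ROI.

    The box is clipped to the fan sector; degenerate (e.g. single-pixel)
    ROIs are expanded to at least ``min_size_px`` pixels radially and in
    arc length so entropies over the region stay meaningful.  Every ROI
    pixel lies inside the returned region.
    """
    geom = frame.fan_geometry
    if not frame.roi_mask.any():
        raise EmptyROIError("cannot bound an empty ROI")
    radius, theta = geom.polar(frame.roi_mask.shape)
    r = radius[frame.roi_mask]
    t = theta[frame.roi_mask]
    r_lo, r_hi = float(r.min()), float(r.max())
    t_lo, t_hi = float(t.min()), float(t.max())

    half = min_size_px / 2.0
    if r_hi - r_lo < min_size_px:
        mid = (r_lo + r_hi) / 2.0
        r_lo, r_hi = mid - half, mid + half
    r_lo = max(r_lo, 0.0)
    r_hi = min(r_hi, geom.range_px)
    # angular width measured as arc length at the outer radius
    arc_scale = np.degrees(1.0 / max(r_hi, 1.0))
    if (t_hi - t_lo) < min_size_px * arc_scale:
        mid = (t_lo + t_hi) / 2.0
        t_lo = mid - half * arc_scale
        t_hi = mid + half * arc_scale
    t_lo = max(t_lo, -geom.sweep / 2.0)
    t_hi = min(t_hi, geom.sweep / 2.0)

    inside = ((radius >= r_lo) & (radius <= r_hi) &
              (theta >= t_lo) & (theta <= t_hi) &
              geom.fan_mask(frame.roi_mask.shape))
    return TrapezoidRegion(r_lo=r_lo, r_hi=r_hi, theta_lo=t_lo, theta_hi=t_hi,
                           mask=inside)


def joint_histogram(a: np.ndarray, b: np.ndarray, region: TrapezoidRegion,
                    cfg: CostConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized joint histogram and marginals over the region's pixels.

    Returns ``(joint, p_a, p_b)``: an M x M probability table summing to 1
    and its row/column marginals.  Hard binning at the native gray levels.
    """
    if cfg is None:
        cfg = CostConfig()
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise InvalidInputError("images must share a shape")
    if region.mask.shape != a.shape:
        raise InvalidInputError("region raster does not match image shape")
    if region.n_pixels == 0:
        raise EmptyRegionError("histogram region contains no pixels")
    m = cfg.gray_levels
    av = a[region.mask].astype(np.intp)
    bv = b[region.mask].astype(np.intp)
    counts = np.zeros((m, m), dtype=float)
    np.add.at(counts, (av, bv), 1.0)
    counts += cfg.histogram_epsilon
    joint = counts / counts.sum()
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi_cost(a: np.ndarray, b: np.ndarray, region: TrapezoidRegion,
             cfg: CostConfig | None = None,
             allow_degenerate: bool = False) -> float:
    """NMI cost ``CN = 1 - (h(a)+h(b)) / h(a,b)`` over the region.

    -1 for perfectly correlated images, approaching 0 for independent
    ones.  If both images are constant over the region the joint entropy
    is zero and CN is undefined: a :class:`DegenerateEntropyError` is
    raised unless ``allow_degenerate`` is set, in which case -1 (the
    perfect-correlation value) is returned.
    """
    joint, p_a, p_b = joint_histogram(a, b, region, cfg)
    h_joint = _entropy(joint.ravel())
    if h_joint == 0.0:
        if allow_degenerate:
            return -1.0
        raise DegenerateEntropyError(
            "both images constant over the region; CN undefined")
    return 1.0 - (_entropy(p_a) + _entropy(p_b)) / h_joint


def dice_index(r1: np.ndarray, r2: np.ndarray) -> float:
    """Dice overlap ``2|r1 ∩ r2| / (|r1| + |r2|)`` of two binary masks.

    Symmetric, in [0, 1]; defined as 0 when both masks are empty (no
    evidence of overlap).
    """
    r1 = np.asarray(r1, dtype=bool)
    r2 = np.asarray(r2, dtype=bool)
    if r1.shape != r2.shape:
        raise InvalidInputError("masks must share a shape")
    denom = int(r1.sum()) + int(r2.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((r1 & r2).sum()) / denom


def total_cost(view, frame: EBUSFrame, cfg: CostConfig | None = None,
               region: TrapezoidRegion | None = None,
               allow_degenerate: bool = False) -> dict:
    """Combined cost ``C = CN - CD`` between a virtual view and an EBUS frame.

    ``view`` is a :class:`~ebusreg.renderer.VirtualView` (or anything with
    ``image`` and ``roi_mask``) rendered in the frame's raster geometry.
    The NMI term is evaluated over the ROI-bounding trapezoid of the EBUS
    frame (pass ``region`` to reuse a precomputed one); the Dice term uses
    the full masks.  Returns a dict with keys ``C``, ``CN``, ``CD`` and
    the region bounds.
    """
    if view.image.shape != frame.image.shape:
        raise InvalidInputError("view and frame rasters must share a shape")
    if region is None:
        region = bounding_trapezoid(frame)
    cn = nmi_cost(view.image, frame.image, region, cfg,
                  allow_degenerate=allow_degenerate)
    cd = dice_index(view.roi_mask, frame.roi_mask)
    return {"C": cn - cd, "CN": cn, "CD": cd,
            "region": {"r_lo": region.r_lo, "r_hi": region.r_hi,
                       "theta_lo": region.theta_lo,
                       "theta_hi": region.theta_hi}}
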