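"""CT-based virtual EBUS rendering.

Renders the virtual EBUS view ``ICTp`` at a pose ``p`` by obliquely
resampling the CT volume over the fan-shaped scan plane, together with the
projected target-node ROI mask ``RCTp`` (1 where the sampled label volume
equals the target label, 0 otherwise) and the in-fan indicator.

HU values are trilinearly interpolated and passed through an affine
window (default soft-tissue window [-1000, 200] HU onto the 256 gray
levels, spanning air through airway-wall attenuation); labels are sampled
nearest-neighbour so the binary ROI is preserved.  Volumes are
axis-aligned: world = origin + index * spacing (identity direction
cosines, adequate for the synthetic phantoms this package ships with and
a documented limitation for rotated clinical volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .errors import InvalidInputError
from .geometry import DeviceFrame, FanSpec, Pose, fan_sample_points, pose_to_frame

__all__ = [
    "CTVolume",
    "LabelVolume",
    "VirtualView",
    "GRAY_LEVELS",
    "DEFAULT_HU_WINDOW",
    "hu_window",
    "render_view",
    "write_png",
    "read_png",
]

GRAY_LEVELS = 256  # M: gray levels a rendered pixel can assume
DEFAULT_HU_WINDOW = (-1000.0, 200.0)
TARGET_LABEL = 1   # lymph-node ROI in the label volume
VESSEL_LABEL = 2


@dataclass
class CTVolume:
    """Axis-aligned 3D CT grid in Hounsfield units.

    ``hu`` is indexed (x, y, z); ``spacing`` and ``origin`` are world mm.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise InvalidInputError("CT volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise InvalidInputError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.asarray(self.spacing) \
            + np.asarray(self.origin)

    def voxel_index(self, point: np.ndarray) -> tuple[int, int, int]:
        """Integer index of the voxel containing a world point (nearest centre)."""
        idx = np.rint(self.world_to_index(point)).astype(int)
        return tuple(idx)

    def contains(self, point: np.ndarray) -> bool:
        """True iff the point rounds to a voxel index inside the grid."""
        idx = self.world_to_index(point)
        return bool(np.all(idx >= -0.5) and
                    np.all(idx < np.asarray(self.shape) - 0.5))

    def hu_at_voxel(self, point: np.ndarray) -> float:
        """HU of the voxel containing a world point; raises if outside."""
        idx = self.voxel_index(point)
        if any(i < 0 or i >= n for i, n in zip(idx, self.shape)):
            raise InvalidInputError(f"point {point} outside volume")
        return float(self.hu[idx])

    # -- NIfTI I/O ----------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTVolume":
        img = nib.load(str(path))
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
            raise InvalidInputError("only axis-aligned volumes are supported")
        spacing = tuple(float(v) for v in np.diag(affine[:3, :3]))
        origin = tuple(float(v) for v in affine[:3, 3])
        return cls(hu=np.asarray(img.dataobj, dtype=np.float32),
                   spacing=spacing, origin=origin)


@dataclass
class LabelVolume:
    """Integer label grid aligned with a :class:`CTVolume` (0 background,
    1 target node, 2 vessel)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise InvalidInputError("label volume must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        vol = CTVolume.from_nifti(path)
        return cls(labels=vol.hu.astype(np.int16), spacing=vol.spacing,
                   origin=vol.origin)


@dataclass
class VirtualView:
    """Rendered virtual EBUS view: gray image, projected ROI, fan indicator."""

    image: np.ndarray      # uint8, (H, W)
    roi_mask: np.ndarray   # bool, (H, W); subset of fan_mask
    fan_mask: np.ndarray   # bool, (H, W)
    pose: Pose = field(default_factory=Pose)

    def __post_init__(self) -> None:
        if not (self.image.shape == self.roi_mask.shape == self.fan_mask.shape):
            raise InvalidInputError("view rasters must share one shape")


def hu_window(hu_value, window: tuple[float, float] = DEFAULT_HU_WINDOW,
              levels: int = GRAY_LEVELS):
    """Affine clamp-and-scale of HU values onto ``[0, levels-1]`` gray levels.

    Values at or below the window floor map to 0, at or above the ceiling
    to ``levels - 1``; in between the map is affine with round-half-to-even
    (the window midpoint of the default 256-level map rounds to 128).
    Accepts scalars or arrays.
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidInputError(f"window must satisfy lo < hi, got {window}")
    x = np.clip(np.asarray(hu_value, dtype=float), lo, hi)
    g = np.rint((x - lo) / (hi - lo) * (levels - 1)).astype(np.uint8)
    return g if g.ndim else g[()]


def render_view(ct: CTVolume, labels: LabelVolume | None, pose: Pose,
                spec: FanSpec | None = None,
                window: tuple[float, float] = DEFAULT_HU_WINDOW,
                target_label: int = TARGET_LABEL,
                frame: DeviceFrame | None = None) -> VirtualView:
    """Render the virtual EBUS view ``ICTp`` and projected ROI ``RCTp``.

    In-fan pixels sample the CT trilinearly at their 3D scan-plane points
    and are windowed to gray; out-of-fan (and out-of-volume) pixels are 0.
    The ROI mask is 1 where the nearest-neighbour label equals
    ``target_label``, restricted to the fan.  Deterministic.
    """
    if spec is None:
        spec = FanSpec()
    if labels is not None and labels.shape != ct.shape:
        raise InvalidInputError(
            f"label shape {labels.shape} != CT shape {ct.shape}")
    if frame is None:
        frame = pose_to_frame(pose, spec)
    points, in_fan = fan_sample_points(frame, spec)

    idx = ct.world_to_index(points[in_fan])  # (N, 3) continuous indices
    coords = idx.T
    hu = map_coordinates(ct.hu, coords, order=1, mode="constant",
                         cval=float(window[0]))
    image = np.zeros(in_fan.shape, dtype=np.uint8)
    image[in_fan] = hu_window(hu, window)

    roi = np.zeros(in_fan.shape, dtype=bool)
    if labels is not None:
        lab = map_coordinates(labels.labels, coords, order=0, mode="constant",
                              cval=0)
        roi[in_fan] = lab == target_label
    return VirtualView(image=image, roi_mask=roi, fan_mask=in_fan, pose=pose)


# -- PNG I/O ---------------------------------------------------------------

def write_png(path: str | Path, raster: np.ndarray) -> None:
    """Write a gray image (uint8) or binary mask (bool -> 0/255) as PNG."""
    arr = np.asarray(raster)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8), mode="L").save(str(path))


def read_png(path: str | Path, as_mask: bool = False) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr > 127 if as_mask else arr
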