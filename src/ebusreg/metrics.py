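"""Error metrics between a registered pose and a ground-truth pose.

Three scalar metrics quantify registration quality:

* position difference ``ep = ||po - pG||`` (mm) — error of the device
  position on the airway surface;
* direction error ``ed = arccos(do . dG)`` (degrees) — angle between the
  two device direction vectors;
* needle difference ``eN = ||(po + lN do) - (pG + lN dG)||`` (mm) —
  distance between the tips of biopsy needles extended a length ``lN``
  along each direction, i.e. the potential biopsy error.

The direction vector of a pose defaults to the probe axis ``n_us`` (the
biopsy needle exits along the scan plane); the tip axis ``n_b`` can be
selected instead.  The needle extension ``lN`` defaults to 20 mm, a
typical transbronchial-needle throw, and is always reported alongside
``eN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .geometry import FanSpec, Pose, pose_to_frame

__all__ = [
    "ErrorMetrics",
    "position_error",
    "direction_error",
    "needle_error",
    "evaluate_poses",
    "DEFAULT_NEEDLE_LENGTH",
]

DEFAULT_NEEDLE_LENGTH = 20.0  # mm


@dataclass(frozen=True)
class ErrorMetrics:
    """Bundle of the three pose-error metrics (plus the lN used)."""

    ep: float  # mm
    ed: float  # degrees
    eN: float  # mm
    lN: float  # mm

    def to_dict(self) -> dict:
        return {"ep": self.ep, "ed": self.ed, "eN": self.eN, "lN": self.lN}


def position_error(po: np.ndarray, pG: np.ndarray) -> float:
    """Euclidean distance ``||po - pG||`` in mm."""
    po = np.asarray(po, dtype=float)
    pG = np.asarray(pG, dtype=float)
    if not (np.all(np.isfinite(po)) and np.all(np.isfinite(pG))):
        raise InvalidInputError("positions must be finite")
    return float(np.linalg.norm(po - pG))


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12 or not np.isfinite(n):
        raise InvalidInputError("direction vector must be nonzero and finite")
    return v / n


def direction_error(do: np.ndarray, dG: np.ndarray) -> float:
    """Angle ``arccos(do . dG)`` between two directions, in degrees [0, 180].

    Inputs are normalized internally; the dot product is clamped to
    [-1, 1] before the arccos so numerically parallel vectors give 0.
    """
    d = float(np.clip(_unit(do) @ _unit(dG), -1.0, 1.0))
    return math.degrees(math.acos(d))


def needle_error(po: np.ndarray, do: np.ndarray, pG: np.ndarray,
                 dG: np.ndarray, lN: float = DEFAULT_NEEDLE_LENGTH) -> float:
    """Distance between needle tips extended ``lN`` mm along each direction."""
    if lN < 0:
        raise InvalidInputError("needle length must be >= 0")
    po = np.asarray(po, dtype=float)
    pG = np.asarray(pG, dtype=float)
    return float(np.linalg.norm((po + lN * _unit(do)) - (pG + lN * _unit(dG))))


def evaluate_poses(po: Pose, pG: Pose, lN: float = DEFAULT_NEEDLE_LENGTH,
                   axis: str = "probe",
                   fan: FanSpec | None = None) -> ErrorMetrics:
    """All three metrics between a registered and a ground-truth pose.

    ``axis`` selects the direction vector: ``'probe'`` for the ultrasound
    axis ``n_us`` (default) or ``'tip'`` for the scope axis ``n_b``.
    """
    if axis not in ("probe", "tip"):
        raise InvalidInputError(f"axis must be 'probe' or 'tip', got {axis!r}")
    if fan is None:
        fan = FanSpec()
    fo = pose_to_frame(po, fan)
    fG = pose_to_frame(pG, fan)
    do = fo.n_us if axis == "probe" else fo.n_b
    dG = fG.n_us if axis == "probe" else fG.n_b
    return ErrorMetrics(
        ep=position_error(po.position, pG.position),
        ed=direction_error(do, dG),
        eN=needle_error(po.position, do, pG.position, dG, lN),
        lN=float(lN),
    )
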