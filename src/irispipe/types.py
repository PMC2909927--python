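"""Core containers shared across pipeline stages.

Conventions
-----------
* Images are 2-D ``float64`` arrays with intensities in ``[0, 1]``, indexed
  ``(row, col)`` with the origin at the top-left (0-based).
* Angles are measured from the positive column axis, increasing
  counter-clockwise in image coordinates, i.e. the unit direction for angle
  ``theta`` is ``(-sin(theta), cos(theta))`` in ``(row, col)`` order.
* Circle radii are in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Circle",
    "SegmentationResult",
    "GroundTruth",
    "PolarIris",
    "IrisCode",
    "MatchResult",
    "ErrorCategory",
]


@dataclass(frozen=True)
class Circle:
    """A circle in image coordinates: subpixel center ``(row, col)``, radius in px."""

    row: float
    col: float
    radius: float

    def __post_init__(self):
        if not (math.isfinite(self.row) and math.isfinite(self.col)):
            raise InvalidArgumentError("circle center must be finite")
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise InvalidArgumentError(f"circle radius must be > 0, got {self.radius}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.row, self.col)

    def center_distance(self, other: "Circle") -> float:
        return math.hypot(self.row - other.row, self.col - other.col)

    def point_at(self, theta: float) -> tuple[float, float]:
        """Boundary point at angle ``theta`` (see module angle convention)."""
        return (self.row - self.radius * math.sin(theta),
                self.col + self.radius * math.cos(theta))

    def contains_point(self, row: float, col: float) -> bool:
        return math.hypot(row - self.row, col - self.col) <= self.radius


@dataclass
class SegmentationResult:
    """Detected pupil and limbal boundaries plus the method that produced them."""

    pupil: Circle
    limbal: Circle
    method: str
    pupil_score: float | None = None
    limbal_score: float | None = None
    warnings: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def containment_slack(self) -> float:
        """``limbal.radius - (center distance + pupil.radius)``; >= -1 px required."""
        return self.limbal.radius - (self.pupil.center_distance(self.limbal)
                                     + self.pupil.radius)


@dataclass
class GroundTruth:
    """Exact boundaries and occlusion mask of a synthetic eye."""

    pupil: Circle
    limbal: Circle
    occlusion_mask: np.ndarray  # bool, image dimensions, True = occluded

    def __post_init__(self):
        m = np.asarray(self.occlusion_mask, dtype=bool)
        if m.ndim != 2:
            raise InvalidArgumentError("occlusion mask must be 2-D")
        self.occlusion_mask = m


@dataclass
class PolarIris:
    """Dimensionless polar remap of the iris annulus (rubber-sheet output).

    ``values`` has shape ``(radial_res, angular_res)`` regardless of pupil size;
    ``valid`` is False wherever the source sample was occluded or off-image.
    """

    values: np.ndarray
    valid: np.ndarray
    seg: SegmentationResult | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if v.ndim != 2 or v.shape != m.shape:
            raise InvalidArgumentError("polar values/valid must be 2-D and congruent")
        self.values, self.valid = v, m

    @property
    def radial_res(self) -> int:
        return self.values.shape[0]

    @property
    def angular_res(self) -> int:
        return self.values.shape[1]


@dataclass
class IrisCode:
    """Binary phase code: two bits per polar pixel, plus matching mask bits.

    ``bits`` and ``mask`` have shape ``(radial_res, angular_res, 2)``; a mask bit
    of True means the bit is valid for matching.  Total length is
    ``2 * radial_res * angular_res``.
    """

    bits: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=bool)
        m = np.asarray(self.mask, dtype=bool)
        if b.ndim != 3 or b.shape[2] != 2 or b.shape != m.shape:
            raise InvalidArgumentError(
                "code bits/mask must have congruent (radial, angular, 2) shape")
        self.bits, self.mask = b, m

    @property
    def length(self) -> int:
        return self.bits.size

    def rolled(self, shift: int) -> "IrisCode":
        """Code with polar columns circularly shifted by ``shift`` bit-pairs."""
        return IrisCode(np.roll(self.bits, shift, axis=1),
                        np.roll(self.mask, shift, axis=1), dict(self.meta))

    def complemented(self) -> "IrisCode":
        return IrisCode(~self.bits, self.mask.copy(), dict(self.meta))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of comparing two iris codes."""

    hd: float
    best_shift: int
    valid_bits: int
    decision: bool
    criterion: float


@dataclass(frozen=True)
class ErrorCategory:
    """Segmentation error class against ground truth.

    ``displacement`` is the max over the two boundaries of
    (Euclidean center offset + |radius error|) in pixels.
    """

    label: str  # "success" | "slight" | "extreme"
    displacement: float
    pupil_displacement: float
    limbal_displacement: float
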