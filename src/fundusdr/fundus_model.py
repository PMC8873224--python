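"""Core domain types and disc/fovea-anchored retinal geometry.

All coordinates are 0-based pixel coordinates, x to the right and y down
(image convention).  Distances are expressed in disc-diameter (DD) units so
that the pixel scale of a particular camera cancels out.  The retina is
partitioned into five concentric regions around the fovea and, for the
quadrant-counting severity rules, into four fovea-centred quadrants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

__all__ = [
    "LesionType",
    "Eye",
    "Lesion",
    "FundusGeometry",
    "ImageRecord",
    "REGION_BOUNDS_DD",
    "N_REGIONS",
    "distance_dd",
    "assign_region",
    "assign_quadrant",
]

Point = Tuple[float, float]


class LesionType(enum.Enum):
    """Closed enumeration of annotatable lesion labels.

    ``ARTEFACT`` marks a non-pathological detection (dust, reflection,
    pigment) and never contributes to any retinopathy grade.
    """

    MA = "MA"
    HAEMORRHAGE = "HAEMORRHAGE"
    BLOT_HAEMORRHAGE = "BLOT_HAEMORRHAGE"
    EXUDATE = "EXUDATE"
    CWS = "CWS"
    VENOUS_BEADING = "VENOUS_BEADING"
    VENOUS_REDUPLICATION = "VENOUS_REDUPLICATION"
    VENOUS_LOOP = "VENOUS_LOOP"
    IRMA = "IRMA"
    NVD = "NVD"
    NVE = "NVE"
    PRERETINAL_HAEMORRHAGE = "PRERETINAL_HAEMORRHAGE"
    FIBROSIS = "FIBROSIS"
    SCAR = "SCAR"
    ARTEFACT = "ARTEFACT"

    @classmethod
    def parse(cls, label: str) -> "LesionType":
        """Parse a string label; unknown labels are rejected."""
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise ValueError(
                f"unknown lesion type {label!r}; valid types are: {valid}"
            ) from None


#: Gradeable lesion types in a fixed, documented order (ARTEFACT excluded).
DR_LESION_TYPES: Tuple[LesionType, ...] = tuple(
    t for t in LesionType if t is not LesionType.ARTEFACT
)


class Eye(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UNKNOWN = "UNKNOWN"


def _check_finite_point(p: Sequence[float], what: str = "point") -> Point:
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"{what} must be finite, got ({x}, {y})")
    return (x, y)


@dataclass(frozen=True)
class Lesion:
    """One detected or annotated pathological feature."""

    type: LesionType
    centroid: Point
    area: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", _check_finite_point(self.centroid, "centroid"))
        if not (self.area >= 0):
            raise ValueError(f"lesion area must be >= 0, got {self.area}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class FundusGeometry:
    """Anatomical landmarks defining the retinal coordinate frame.

    The optic-disc diameter is the distance unit; the fovea centre is the
    origin of the concentric region partition.
    """

    disc_centre: Point
    disc_diameter: float
    fovea_centre: Point
    image_width: int = 0
    image_height: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "disc_centre", _check_finite_point(self.disc_centre, "disc_centre"))
        object.__setattr__(self, "fovea_centre", _check_finite_point(self.fovea_centre, "fovea_centre"))
        if not (self.disc_diameter > 0):
            raise ValueError(f"disc_diameter must be > 0, got {self.disc_diameter}")
        if self.disc_centre == self.fovea_centre:
            raise ValueError("disc_centre and fovea_centre must be distinct")
        if self.image_width < 0 or self.image_height < 0:
            raise ValueError("image dimensions must be non-negative")


@dataclass
class ImageRecord:
    """One fundus image: identity, landmarks and its lesion annotation set."""

    image_id: str
    geometry: FundusGeometry
    lesions: list[Lesion] = field(default_factory=list)
    eye: Eye = Eye.UNKNOWN
    capture_time: str = ""
    gradable: bool = True

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")


#: Upper edge (in DD from fovea) of regions 1..4; region 5 is everything beyond.
REGION_BOUNDS_DD: Tuple[float, ...] = (1.0, 1.5, 2.0, 3.0)
N_REGIONS = 5


def distance_dd(point: Sequence[float], geometry: FundusGeometry) -> float:
    """Euclidean distance from *point* to the fovea in disc-diameter units."""
    x, y = _check_finite_point(point)
    fx, fy = geometry.fovea_centre
    return math.hypot(x - fx, y - fy) / geometry.disc_diameter


def assign_region(point: Sequence[float], geometry: FundusGeometry) -> int:
    """Five-region concentric partition around the fovea.

    Region 1: within 1 DD of the fovea; region 2: (1, 1.5] DD; region 3:
    (1.5, 2] DD; region 4: (2, 3] DD; region 5: beyond 3 DD.  Boundaries are
    upper-edge inclusive so the five regions totally partition the plane.
    """
    d = distance_dd(point, geometry)
    for idx, bound in enumerate(REGION_BOUNDS_DD, start=1):
        if d <= bound:
            return idx
    return 5


def assign_quadrant(point: Sequence[float], geometry: FundusGeometry) -> int:
    """Fovea-centred axis-aligned quadrant of *point*.

    Numbering starts at 1 in the upper-right (x > fovea x, y < fovea y in
    image coordinates) and proceeds counter-clockwise as displayed: 2 is
    upper-left, 3 lower-left, 4 lower-right.  Points exactly on an axis are
    assigned to the lower-numbered adjacent quadrant.
    """
    x, y = _check_finite_point(point)
    fx, fy = geometry.fovea_centre
    dx, dy = x - fx, y - fy
    # closed-quadrant membership; ties resolve to the smallest index
    if dx >= 0 and dy <= 0:
        return 1
    if dx <= 0 and dy <= 0:
        return 2
    if dx <= 0 and dy >= 0:
        return 3
    return 4


def region_counts(points: Iterable[Sequence[float]], geometry: FundusGeometry) -> list[int]:
    """Histogram of region indices (length 5) for an iterable of points."""
    counts = [0] * N_REGIONS
    for p in points:
        counts[assign_region(p, geometry) - 1] += 1
    return counts
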