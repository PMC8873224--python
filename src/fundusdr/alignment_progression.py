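"""Landmark-based registration and lesion-level longitudinal change analysis.

Baseline and follow-up images of the same eye are registered by the unique
similarity transform mapping the baseline optic-disc and fovea centres onto
the follow-up ones (two point pairs fully determine the four degrees of
freedom in closed form).  Mapped baseline lesions are then matched per type
to follow-up lesions by greedy nearest-neighbour within a disc-diameter
radius, and each pairing is classified as NEW / RESOLVED / GROWN / SHRUNK /
STABLE.  Events are attributed to the five-region partition of the
follow-up frame.
"""

from __future__ import annotations

import cmath
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .fundus_model import (
    FundusGeometry,
    ImageRecord,
    Lesion,
    LesionType,
    assign_region,
)
from .grading import (
    DecisionTable,
    GradeResult,
    ReferabilityPolicy,
    default_table,
    grade,
    summarise,
)

__all__ = [
    "SimilarityTransform",
    "ChangeKind",
    "ChangeEvent",
    "ProgressionReport",
    "ProgressionConfig",
    "fit_landmark_transform",
    "map_lesions",
    "match_lesions",
    "compare_visits",
]

DEFAULT_MATCH_RADIUS_DD = 0.25
DEFAULT_AREA_DEADBAND = 0.2


class DegenerateGeometryError(ValueError):
    """Disc and fovea coincide; the landmark transform is underdetermined."""


@dataclass(frozen=True)
class SimilarityTransform:
    """4-DOF similarity: rotate by ``rotation``, scale, then translate."""

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (-math.pi < self.rotation <= math.pi):
            raise ValueError(f"rotation must lie in (-pi, pi], got {self.rotation}")

    def apply(self, point: Sequence[float]) -> tuple[float, float]:
        z = complex(point[0], point[1])
        a = self.scale * cmath.exp(1j * self.rotation)
        w = a * z + complex(*self.translation)
        return (w.real, w.imag)

    def inverse(self) -> "SimilarityTransform":
        a = self.scale * cmath.exp(1j * self.rotation)
        b = complex(*self.translation)
        ai = 1.0 / a
        bi = -b * ai
        return SimilarityTransform(
            scale=abs(ai),
            rotation=_wrap_angle(cmath.phase(ai)),
            translation=(bi.real, bi.imag),
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        a1 = self.scale * cmath.exp(1j * self.rotation)
        a2 = other.scale * cmath.exp(1j * other.rotation)
        b1 = complex(*self.translation)
        b2 = complex(*other.translation)
        a = a1 * a2
        b = a1 * b2 + b1
        return SimilarityTransform(
            scale=abs(a),
            rotation=_wrap_angle(cmath.phase(a)),
            translation=(b.real, b.imag),
        )

    def apply_geometry(self, geometry: FundusGeometry) -> FundusGeometry:
        return FundusGeometry(
            disc_centre=self.apply(geometry.disc_centre),
            disc_diameter=geometry.disc_diameter * self.scale,
            fovea_centre=self.apply(geometry.fovea_centre),
            image_width=geometry.image_width,
            image_height=geometry.image_height,
        )


def _wrap_angle(theta: float) -> float:
    theta = math.remainder(theta, 2 * math.pi)
    if theta <= -math.pi:
        theta += 2 * math.pi
    return theta


def fit_landmark_transform(baseline: FundusGeometry,
                           followup: FundusGeometry) -> SimilarityTransform:
    """Closed-form similarity mapping baseline landmarks onto follow-up ones.

    With points as complex numbers the map is ``z -> a z + b``; two point
    correspondences (disc and fovea) determine ``a`` and ``b`` exactly.
    """
    d0 = complex(*baseline.disc_centre)
    f0 = complex(*baseline.fovea_centre)
    d1 = complex(*followup.disc_centre)
    f1 = complex(*followup.fovea_centre)
    if d0 == f0 or d1 == f1:
        raise DegenerateGeometryError("disc and fovea centres coincide")
    a = (d1 - f1) / (d0 - f0)
    b = f1 - a * f0
    return SimilarityTransform(
        scale=abs(a),
        rotation=_wrap_angle(cmath.phase(a)),
        translation=(b.real, b.imag),
    )


def map_lesions(lesions: Sequence[Lesion], t: SimilarityTransform) -> list[Lesion]:
    """Transform lesion centroids; areas scale with the Jacobian (scale²)."""
    jac = t.scale ** 2
    return [replace(l, centroid=t.apply(l.centroid), area=l.area * jac) for l in lesions]


def match_lesions(baseline: Sequence[Lesion], followup: Sequence[Lesion],
                  match_radius_dd: float, geometry: FundusGeometry,
                  ) -> list[tuple[Optional[int], Optional[int]]]:
    """Greedy per-type nearest-neighbour matching in the follow-up frame.

    Candidate pairs within ``match_radius_dd * disc_diameter`` are accepted
    in increasing distance order (ties break toward lower ids); unmatched
    lesions of either visit yield one-sided entries.  Baseline lesions are
    expected to have been mapped into the follow-up frame already.
    """
    if not (match_radius_dd > 0):
        raise ValueError(f"match radius must be positive, got {match_radius_dd}")
    max_dist = match_radius_dd * geometry.disc_diameter
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    for t in LesionType:
        b_ids = [i for i, l in enumerate(baseline) if l.type is t]
        f_ids = [j for j, l in enumerate(followup) if l.type is t]
        candidates = []
        for i in b_ids:
            for j in f_ids:
                d = math.dist(baseline[i].centroid, followup[j].centroid)
                if d <= max_dist:
                    candidates.append((d, i, j))
        candidates.sort()
        used_b: set[int] = set()
        used_f: set[int] = set()
        for _, i, j in candidates:
            if i in used_b or j in used_f:
                continue
            used_b.add(i)
            used_f.add(j)
            pairs.append((i, j))
        pairs.extend((i, None) for i in b_ids if i not in used_b)
        pairs.extend((None, j) for j in f_ids if j not in used_f)
    pairs.sort(key=lambda p: (p[0] is None, p[0] if p[0] is not None else p[1]))
    return pairs


class ChangeKind(enum.Enum):
    NEW = "NEW"
    RESOLVED = "RESOLVED"
    GROWN = "GROWN"
    SHRUNK = "SHRUNK"
    STABLE = "STABLE"


@dataclass(frozen=True)
class ChangeEvent:
    """One lesion-level change between two visits of the same eye."""

    kind: ChangeKind
    lesion_type: LesionType
    region: int
    baseline_lesion_id: Optional[int] = None
    followup_lesion_id: Optional[int] = None
    area_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is ChangeKind.NEW and self.baseline_lesion_id is not None:
            raise ValueError("NEW events carry no baseline lesion id")
        if self.kind is ChangeKind.RESOLVED and self.followup_lesion_id is not None:
            raise ValueError("RESOLVED events carry no follow-up lesion id")
        if self.kind in (ChangeKind.GROWN, ChangeKind.SHRUNK, ChangeKind.STABLE):
            if self.baseline_lesion_id is None or self.followup_lesion_id is None:
                raise ValueError(f"{self.kind.value} events need both lesion ids")


def classify_pair(area_ratio: float, deadband: float = DEFAULT_AREA_DEADBAND) -> ChangeKind:
    """GROWN above 1+δ, SHRUNK below 1−δ, STABLE inside the deadband."""
    if area_ratio > 1.0 + deadband:
        return ChangeKind.GROWN
    if area_ratio < 1.0 - deadband:
        return ChangeKind.SHRUNK
    return ChangeKind.STABLE


@dataclass(frozen=True)
class ProgressionConfig:
    scheme: str = "ICDRS"
    match_radius_dd: float = DEFAULT_MATCH_RADIUS_DD
    area_deadband: float = DEFAULT_AREA_DEADBAND
    conf_threshold: float = 0.0
    table: Optional[DecisionTable] = None
    policy: Optional[ReferabilityPolicy] = None


@dataclass
class ProgressionReport:
    """Change log between two visits plus both visits' severity grades."""

    events: list[ChangeEvent]
    transform: SimilarityTransform
    baseline_grade: GradeResult
    followup_grade: GradeResult
    grade_delta: int
    kind_counts: dict[ChangeKind, int] = field(default_factory=dict)
    region_kind_counts: dict[int, dict[ChangeKind, int]] = field(default_factory=dict)
    type_kind_counts: dict[LesionType, dict[ChangeKind, int]] = field(default_factory=dict)


def _aggregate(events: Sequence[ChangeEvent]) -> tuple[dict, dict, dict]:
    kind_counts = {k: 0 for k in ChangeKind}
    region_counts: dict[int, dict[ChangeKind, int]] = {r: {k: 0 for k in ChangeKind} for r in range(1, 6)}
    type_counts: dict[LesionType, dict[ChangeKind, int]] = {}
    for ev in events:
        kind_counts[ev.kind] += 1
        region_counts[ev.region][ev.kind] += 1
        type_counts.setdefault(ev.lesion_type, {k: 0 for k in ChangeKind})[ev.kind] += 1
    return kind_counts, region_counts, type_counts


def compare_visits(baseline: ImageRecord, followup: ImageRecord,
                   config: ProgressionConfig = ProgressionConfig()) -> ProgressionReport:
    """Full progression pipeline between two visits of one eye.

    Registers the baseline into the follow-up frame from the disc/fovea
    landmarks, matches lesions per type, classifies each pairing, and
    aggregates events per region (computed in the follow-up frame).
    """
    if baseline.eye != followup.eye:
        raise ValueError(f"eye mismatch: {baseline.eye.value} vs {followup.eye.value}")
    if not (baseline.gradable and followup.gradable):
        raise ValueError("both visits must be gradable for progression analysis")
    t = fit_landmark_transform(baseline.geometry, followup.geometry)
    mapped = map_lesions(baseline.lesions, t)
    geom = followup.geometry
    pairs = match_lesions(mapped, followup.lesions, config.match_radius_dd, geom)
    events: list[ChangeEvent] = []
    for b_id, f_id in pairs:
        if b_id is None:
            lesion = followup.lesions[f_id]
            events.append(ChangeEvent(ChangeKind.NEW, lesion.type,
                                      assign_region(lesion.centroid, geom),
                                      followup_lesion_id=f_id))
        elif f_id is None:
            lesion = mapped[b_id]
            events.append(ChangeEvent(ChangeKind.RESOLVED, lesion.type,
                                      assign_region(lesion.centroid, geom),
                                      baseline_lesion_id=b_id))
        else:
            b_lesion, f_lesion = mapped[b_id], followup.lesions[f_id]
            ratio = f_lesion.area / b_lesion.area if b_lesion.area > 0 else math.inf
            kind = classify_pair(ratio, config.area_deadband)
            events.append(ChangeEvent(kind, f_lesion.type,
                                      assign_region(f_lesion.centroid, geom),
                                      baseline_lesion_id=b_id,
                                      followup_lesion_id=f_id,
                                      area_ratio=ratio))
    table = config.table if config.table is not None else default_table(config.scheme)
    g0 = grade(summarise(baseline, config.conf_threshold), table, config.policy)
    g1 = grade(summarise(followup, config.conf_threshold), table, config.policy)
    kind_counts, region_counts, type_counts = _aggregate(events)
    return ProgressionReport(
        events=events,
        transform=t,
        baseline_grade=g0,
        followup_grade=g1,
        grade_delta=g1.level_index - g0.level_index,
        kind_counts=kind_counts,
        region_kind_counts=region_counts,
        type_kind_counts=type_counts,
    )
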