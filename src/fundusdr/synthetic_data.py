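"""Synthetic graded cohorts, detector noise, longitudinal pairs and phantoms.

Lesion sets are synthesised by inverting the grading decision tables: for a
requested severity level a lesion configuration is drawn that satisfies the
target level's rule and provably fails every higher rule, then verified by
running the grader.  Cohorts mix levels according to configurable
prevalence presets; a noise model corrupts the detector channel (misses,
false alarms, centroid/area jitter, confidence draws); longitudinal pairs
plant an exact ground-truth change script behind a camera-frame
perturbation.  A deliberately simple raster phantom renderer and
blob-detector stand in for the out-of-scope learned detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .alignment_progression import ChangeEvent, ChangeKind, SimilarityTransform, map_lesions
from .fundus_model import (
    DR_LESION_TYPES,
    Eye,
    FundusGeometry,
    ImageRecord,
    Lesion,
    LesionType,
    assign_region,
    distance_dd,
)
from .grading import DecisionTable, default_table, grade, summarise

__all__ = [
    "PrevalenceConfig",
    "NoiseModel",
    "ProgressionScript",
    "PlannedEvent",
    "InfeasibleSynthesisError",
    "default_geometry",
    "prevalence_preset",
    "PRESET_COUNTS",
    "synthesise_for_level",
    "apply_noise",
    "sample_cohort",
    "synthesise_pair",
    "render_phantom",
    "demo_detect",
]


class InfeasibleSynthesisError(ValueError):
    """The requested (level, maculopathy) combination has no witness set."""


def default_geometry(width: int = 1200, height: int = 1200,
                     disc_diameter: float = 120.0) -> FundusGeometry:
    """A canonical macula-centred frame: fovea mid-image, disc 2.5 DD temporal."""
    fovea = (width / 2.0, height / 2.0)
    disc = (fovea[0] + 2.5 * disc_diameter, fovea[1])
    return FundusGeometry(disc_centre=disc, disc_diameter=disc_diameter,
                          fovea_centre=fovea, image_width=width, image_height=height)


# ---------------------------------------------------------------------------
# Prevalence presets
# ---------------------------------------------------------------------------

#: Per-grade image counts of the three reference screening cohorts.
PRESET_COUNTS: Mapping[str, tuple[str, tuple[int, ...]]] = {
    "kenya": ("ICDRS", (13304, 10967, 3935, 381, 93)),
    "saudi": ("NSC", (7451, 1854, 582, 139)),
    "china": ("NSC", (9986, 3279, 1240, 495)),
}


@dataclass(frozen=True)
class PrevalenceConfig:
    """Per-level sampling proportions for a cohort, plus maculopathy rates."""

    scheme: str
    levels: tuple[str, ...]
    proportions: tuple[float, ...]
    maculopathy_rate: Mapping[str, float] = field(default_factory=dict)
    counts: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.proportions):
            raise ValueError("levels and proportions differ in length")
        total = sum(self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")
        for level, rate in self.maculopathy_rate.items():
            if level not in self.levels:
                raise ValueError(f"maculopathy rate for unknown level {level!r}")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"maculopathy rate must be in [0, 1], got {rate}")

    @property
    def total_images(self) -> Optional[int]:
        return None if self.counts is None else sum(self.counts)


def prevalence_preset(name: str) -> PrevalenceConfig:
    """Load one of the three shipped cohort presets (kenya / saudi / china)."""
    try:
        scheme, counts = PRESET_COUNTS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_COUNTS)}") from None
    levels = default_table(scheme).levels
    total = sum(counts)
    return PrevalenceConfig(
        scheme=scheme,
        levels=levels,
        proportions=tuple(c / total for c in counts),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Level-targeted lesion synthesis
# ---------------------------------------------------------------------------

_AREA_RANGES: Mapping[LesionType, tuple[float, float]] = {
    LesionType.MA: (5, 25),
    LesionType.HAEMORRHAGE: (40, 400),
    LesionType.BLOT_HAEMORRHAGE: (100, 600),
    LesionType.EXUDATE: (30, 250),
    LesionType.CWS: (80, 500),
    LesionType.VENOUS_BEADING: (50, 300),
    LesionType.VENOUS_REDUPLICATION: (50, 300),
    LesionType.VENOUS_LOOP: (50, 300),
    LesionType.IRMA: (40, 250),
    LesionType.NVD: (100, 800),
    LesionType.NVE: (100, 800),
    LesionType.PRERETINAL_HAEMORRHAGE: (200, 1500),
    LesionType.FIBROSIS: (200, 1500),
    LesionType.SCAR: (100, 900),
    LesionType.ARTEFACT: (10, 200),
}

#: radial DD bounds of the five regions used when sampling positions
_REGION_RADII = {1: (0.05, 0.95), 2: (1.05, 1.45), 3: (1.55, 1.95),
                 4: (2.05, 2.95), 5: (3.05, 3.80)}

#: atan2 angle ranges (y down) of the four fovea-centred quadrants
_QUADRANT_ANGLES = {1: (-math.pi / 2, 0.0), 2: (-math.pi, -math.pi / 2),
                    3: (math.pi / 2, math.pi), 4: (0.0, math.pi / 2)}


def _sample_point(rng: np.random.Generator, geometry: FundusGeometry,
                  region: Optional[int] = None, quadrant: Optional[int] = None,
                  min_dd: Optional[float] = None, max_dd: Optional[float] = None,
                  ) -> tuple[float, float]:
    lo, hi = _REGION_RADII[region] if region is not None else (0.05, 3.80)
    if min_dd is not None:
        lo = max(lo, min_dd)
    if max_dd is not None:
        hi = min(hi, max_dd)
    a_lo, a_hi = _QUADRANT_ANGLES[quadrant] if quadrant is not None else (-math.pi, math.pi)
    eps = 0.02
    r = rng.uniform(lo, hi) * geometry.disc_diameter
    theta = rng.uniform(a_lo + eps, a_hi - eps)
    fx, fy = geometry.fovea_centre
    return (fx + r * math.cos(theta), fy + r * math.sin(theta))


def _make_lesion(rng: np.random.Generator, t: LesionType, geometry: FundusGeometry,
                 confidence: float = 1.0, **where) -> Lesion:
    lo, hi = _AREA_RANGES[t]
    return Lesion(type=t, centroid=_sample_point(rng, geometry, **where),
                  area=float(rng.uniform(lo, hi)), confidence=confidence)


# exudates placed outside this radius never raise the maculopathy flag
_MAC_SAFE_DD = 1.1

_MAC_INFEASIBLE = {("ICDRS", "0"), ("ICDRS", "1"), ("NSC", "R0")}


def synthesise_for_level(scheme: str, level: str, maculopathy: bool,
                         geometry: FundusGeometry, seed,
                         table: Optional[DecisionTable] = None,
                         image_id: str = "synthetic") -> ImageRecord:
    """Draw a lesion set whose grade under the default table is exactly *level*.

    The result satisfies the target rule and fails every higher one;
    *maculopathy* plants (or avoids) an exudate within the 1-DD macular
    radius.  Combinations with no witness (e.g. maculopathy on a lesion-free
    grade) raise :class:`InfeasibleSynthesisError`.
    """
    table = table if table is not None else default_table(scheme)
    table.level_index(level)  # validates
    if maculopathy and (table.scheme, level) in _MAC_INFEASIBLE:
        raise InfeasibleSynthesisError(
            f"maculopathy requires an exudate, which raises {table.scheme} above level {level}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if table.scheme == "ICDRS":
        lesions = _synth_icdrs(rng, level, maculopathy, geometry)
    elif table.scheme == "NSC":
        lesions = _synth_nsc(rng, level, maculopathy, geometry)
    else:
        raise InfeasibleSynthesisError(f"no synthesiser for scheme {table.scheme!r}")
    record = ImageRecord(image_id=image_id, geometry=geometry, lesions=lesions)
    result = grade(summarise(record, conf_threshold=0.0), table)
    if result.level != level or result.dmo != maculopathy:
        raise InfeasibleSynthesisError(
            f"synthesis self-check failed: wanted ({level}, dmo={maculopathy}), "
            f"got ({result.level}, dmo={result.dmo})")
    return record


def _mac_exudate(rng, geometry) -> Lesion:
    return _make_lesion(rng, LesionType.EXUDATE, geometry, max_dd=0.9, region=1)


def _safe_exudates(rng, geometry, n) -> list[Lesion]:
    return [_make_lesion(rng, LesionType.EXUDATE, geometry, min_dd=_MAC_SAFE_DD)
            for _ in range(n)]


def _background_mas(rng, geometry, lo=1, hi=8) -> list[Lesion]:
    return [_make_lesion(rng, LesionType.MA, geometry)
            for _ in range(int(rng.integers(lo, hi + 1)))]


def _synth_icdrs(rng, level, maculopathy, geometry) -> list[Lesion]:
    lesions: list[Lesion] = []
    if level == "0":
        return lesions
    if level == "1":
        return _background_mas(rng, geometry)
    if level == "2":
        lesions += _background_mas(rng, geometry, 0, 5)
        # moderate witnesses; haemorrhage counts stay far below the 4-2-1 rule
        choices = [LesionType.HAEMORRHAGE, LesionType.CWS,
                   LesionType.VENOUS_LOOP, LesionType.VENOUS_REDUPLICATION]
        picks = rng.choice(len(choices), size=int(rng.integers(1, 3)), replace=False)
        for i in picks:
            lesions += [_make_lesion(rng, choices[i], geometry)
                        for _ in range(int(rng.integers(1, 4)))]
        if rng.random() < 0.5 and not maculopathy:
            lesions += _safe_exudates(rng, geometry, int(rng.integers(1, 3)))
    elif level == "3":
        lesions += _background_mas(rng, geometry, 0, 5)
        branch = int(rng.integers(0, 3))
        if branch == 0:  # >= 20 haemorrhages in each of the four quadrants
            for q in (1, 2, 3, 4):
                for _ in range(int(rng.integers(20, 25))):
                    lesions.append(_make_lesion(rng, LesionType.HAEMORRHAGE,
                                                geometry, quadrant=q, min_dd=0.2, max_dd=2.8))
        elif branch == 1:  # venous beading in >= 2 quadrants
            quads = rng.choice(4, size=int(rng.integers(2, 5)), replace=False) + 1
            for q in quads:
                lesions.append(_make_lesion(rng, LesionType.VENOUS_BEADING,
                                            geometry, quadrant=int(q), min_dd=0.5, max_dd=2.8))
        else:  # IRMA anywhere
            lesions += [_make_lesion(rng, LesionType.IRMA, geometry)
                        for _ in range(int(rng.integers(1, 4)))]
    elif level == "4":
        pdr_types = [LesionType.NVD, LesionType.NVE,
                     LesionType.PRERETINAL_HAEMORRHAGE, LesionType.FIBROSIS,
                     LesionType.SCAR]
        picks = rng.choice(len(pdr_types), size=int(rng.integers(1, 3)), replace=False)
        lesions += [_make_lesion(rng, pdr_types[i], geometry) for i in picks]
        lesions += _background_mas(rng, geometry, 0, 5)
        if rng.random() < 0.5:
            lesions.append(_make_lesion(rng, LesionType.HAEMORRHAGE, geometry))
    else:
        raise InfeasibleSynthesisError(f"unknown ICDRS level {level!r}")
    if maculopathy:
        lesions.append(_mac_exudate(rng, geometry))
    return lesions


def _synth_nsc(rng, level, maculopathy, geometry) -> list[Lesion]:
    lesions: list[Lesion] = []
    if level == "R0":
        return lesions
    if level == "R1":
        choices = [LesionType.MA, LesionType.HAEMORRHAGE, LesionType.CWS]
        picks = rng.choice(len(choices), size=int(rng.integers(1, 4)), replace=False)
        for i in picks:
            lesions += [_make_lesion(rng, choices[i], geometry)
                        for _ in range(int(rng.integers(1, 5)))]
        if rng.random() < 0.5 and not maculopathy:
            lesions += _safe_exudates(rng, geometry, int(rng.integers(1, 3)))
    elif level == "R2":
        lesions += _background_mas(rng, geometry, 0, 5)
        branch = int(rng.integers(0, 2))
        if branch == 0:
            pre_types = [LesionType.VENOUS_BEADING, LesionType.VENOUS_LOOP,
                         LesionType.VENOUS_REDUPLICATION, LesionType.IRMA]
            picks = rng.choice(len(pre_types), size=int(rng.integers(1, 3)), replace=False)
            lesions += [_make_lesion(rng, pre_types[i], geometry) for i in picks]
        else:  # multiple blot haemorrhages
            lesions += [_make_lesion(rng, LesionType.BLOT_HAEMORRHAGE, geometry)
                        for _ in range(int(rng.integers(5, 9)))]
    elif level == "R3":
        pdr_types = [LesionType.NVD, LesionType.NVE,
                     LesionType.PRERETINAL_HAEMORRHAGE, LesionType.FIBROSIS,
                     LesionType.SCAR]
        picks = rng.choice(len(pdr_types), size=int(rng.integers(1, 3)), replace=False)
        lesions += [_make_lesion(rng, pdr_types[i], geometry) for i in picks]
        lesions += _background_mas(rng, geometry, 0, 5)
    else:
        raise InfeasibleSynthesisError(f"unknown NSC level {level!r}")
    if maculopathy:
        lesions.append(_mac_exudate(rng, geometry))
    return lesions


# ---------------------------------------------------------------------------
# Detector noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Stochastic corruption of a clean annotation set.

    ``miss_prob`` / ``false_alarm_rate`` may be a scalar applied to every
    lesion type or a per-type mapping; false-alarm rates are Poisson means
    of spurious lesions per image (artefact detections included via an
    ``ARTEFACT`` entry).  Jitters are in DD (centroid) and multiplicative
    log-scale (area).  Confidences are Beta(a, b) draws; ``None`` keeps
    confidence 1.
    """

    miss_prob: float | Mapping[LesionType, float] = 0.0
    false_alarm_rate: float | Mapping[LesionType, float] = 0.0
    centroid_jitter_dd: float = 0.0
    area_jitter_sd: float = 0.0
    confidence_beta: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        for p in self._per_type(self.miss_prob).values():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"miss probability must be in [0, 1], got {p}")
        for r in self._per_type(self.false_alarm_rate).values():
            if r < 0:
                raise ValueError(f"false alarm rate must be >= 0, got {r}")
        if self.centroid_jitter_dd < 0 or self.area_jitter_sd < 0:
            raise ValueError("jitter magnitudes must be >= 0")

    @staticmethod
    def _per_type(value) -> dict[LesionType, float]:
        if isinstance(value, Mapping):
            return {t: float(v) for t, v in value.items()}
        return {t: float(value) for t in LesionType}

    def miss_for(self, t: LesionType) -> float:
        return self._per_type(self.miss_prob).get(t, 0.0)

    def rate_for(self, t: LesionType) -> float:
        return self._per_type(self.false_alarm_rate).get(t, 0.0)

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls()


def apply_noise(record: ImageRecord, noise: NoiseModel,
                rng: np.random.Generator) -> ImageRecord:
    """Corrupt one record's lesion list under the noise model (GT unaffected)."""
    geom = record.geometry
    out: list[Lesion] = []
    for lesion in record.lesions:
        if rng.random() < noise.miss_for(lesion.type):
            continue
        cx, cy = lesion.centroid
        if noise.centroid_jitter_dd > 0:
            sd = noise.centroid_jitter_dd * geom.disc_diameter
            cx += rng.normal(0.0, sd)
            cy += rng.normal(0.0, sd)
        area = lesion.area
        if noise.area_jitter_sd > 0:
            area *= math.exp(rng.normal(0.0, noise.area_jitter_sd))
        conf = lesion.confidence
        if noise.confidence_beta is not None:
            a, b = noise.confidence_beta
            conf = float(rng.beta(a, b))
        out.append(Lesion(type=lesion.type, centroid=(cx, cy), area=area,
                          confidence=conf))
    for t in LesionType:
        rate = noise.rate_for(t)
        if rate <= 0:
            continue
        for _ in range(int(rng.poisson(rate))):
            conf = 1.0
            if noise.confidence_beta is not None:
                a, b = noise.confidence_beta
                conf = float(rng.beta(a, b))
            out.append(_make_lesion(rng, t, geom, confidence=conf))
    return replace_lesions(record, out)


def replace_lesions(record: ImageRecord, lesions: list[Lesion]) -> ImageRecord:
    return ImageRecord(image_id=record.image_id, geometry=record.geometry,
                       lesions=lesions, eye=record.eye,
                       capture_time=record.capture_time, gradable=record.gradable)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortMember:
    record: ImageRecord
    gt_level: str
    gt_maculopathy: bool


def sample_cohort(prevalence: PrevalenceConfig, n: int, noise: NoiseModel,
                  seed: int, geometry: Optional[FundusGeometry] = None,
                  table: Optional[DecisionTable] = None) -> list[CohortMember]:
    """Draw *n* graded records with detector noise; ground truth retained."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    geometry = geometry if geometry is not None else default_geometry()
    table = table if table is not None else default_table(prevalence.scheme)
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for i in range(n):
        level = prevalence.levels[rng.choice(len(prevalence.levels),
                                             p=prevalence.proportions)]
        mac_rate = prevalence.maculopathy_rate.get(level, 0.0)
        mac = bool(rng.random() < mac_rate)
        clean = synthesise_for_level(prevalence.scheme, level, mac, geometry,
                                     rng, table=table, image_id=f"synthetic-{i:06d}")
        noisy = apply_noise(clean, noise, rng)
        members.append(CohortMember(record=noisy, gt_level=level, gt_maculopathy=mac))
    return members


# ---------------------------------------------------------------------------
# Longitudinal pairs with planted change scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedEvent:
    """One scripted lesion change; target_id picks the baseline lesion for
    RESOLVED / GROWN / SHRUNK (None → first untouched lesion of the type)."""

    kind: ChangeKind
    lesion_type: LesionType
    region: Optional[int] = None
    area_factor: Optional[float] = None
    target_id: Optional[int] = None


@dataclass(frozen=True)
class ProgressionScript:
    events: tuple[PlannedEvent, ...]
    camera: SimilarityTransform = SimilarityTransform()


class InapplicableEventError(ValueError):
    """A scripted event has no applicable target in the baseline record."""


def synthesise_pair(baseline: ImageRecord, script: ProgressionScript,
                    noise: NoiseModel, seed: int,
                    min_separation_dd: float = 0.7,
                    ) -> tuple[ImageRecord, list[ChangeEvent]]:
    """Produce a follow-up record realising *script* plus its exact GT change log.

    The camera perturbation is applied to geometry and lesions first, then
    the planted events, then detector noise.  Ground-truth events use the
    same lesion indexing as the records so the recovered change log can be
    compared verbatim.  NEW lesions are rejection-sampled at least
    *min_separation_dd* away from same-type lesions to keep matching
    unambiguous at zero noise.
    """
    rng = np.random.default_rng(seed)
    camera = script.camera
    geom1 = camera.apply_geometry(baseline.geometry)
    mapped = map_lesions(baseline.lesions, camera)

    survivors: list[tuple[int, Lesion]] = [(i, l) for i, l in enumerate(mapped)]
    resolved: list[tuple[int, Lesion]] = []
    area_changes: dict[int, float] = {}
    touched: set[int] = set()

    def _pick_target(ev: PlannedEvent) -> int:
        if ev.target_id is not None:
            if ev.target_id in touched or ev.target_id >= len(mapped) \
                    or baseline.lesions[ev.target_id].type is not ev.lesion_type:
                raise InapplicableEventError(f"event target {ev.target_id} unavailable")
            return ev.target_id
        for i, l in enumerate(baseline.lesions):
            if l.type is ev.lesion_type and i not in touched:
                return i
        raise InapplicableEventError(
            f"no untouched {ev.lesion_type.value} lesion for {ev.kind.value} event")

    new_lesions: list[Lesion] = []
    new_regions: list[int] = []
    for ev in script.events:
        if ev.kind is ChangeKind.NEW:
            region = ev.region if ev.region is not None else int(rng.integers(1, 6))
            lesion = _place_separated(rng, ev.lesion_type, geom1, region,
                                      [l for _, l in survivors] + new_lesions,
                                      min_separation_dd)
            new_lesions.append(lesion)
            new_regions.append(region)
        elif ev.kind is ChangeKind.RESOLVED:
            i = _pick_target(ev)
            touched.add(i)
            lesion = mapped[i]
            survivors = [(j, l) for j, l in survivors if j != i]
            resolved.append((i, lesion))
        elif ev.kind in (ChangeKind.GROWN, ChangeKind.SHRUNK):
            i = _pick_target(ev)
            touched.add(i)
            factor = ev.area_factor if ev.area_factor is not None else \
                (1.5 if ev.kind is ChangeKind.GROWN else 0.5)
            if (ev.kind is ChangeKind.GROWN) != (factor > 1.0):
                raise InapplicableEventError(
                    f"area factor {factor} inconsistent with {ev.kind.value}")
            area_changes[i] = factor
        else:
            raise InapplicableEventError(f"cannot plant a {ev.kind.value} event")

    followup_lesions: list[Lesion] = []
    gt_events: list[ChangeEvent] = []
    for f_idx, (b_id, lesion) in enumerate(survivors):
        if b_id in area_changes:
            factor = area_changes[b_id]
            lesion = replace(lesion, area=lesion.area * factor)
            kind = ChangeKind.GROWN if factor > 1.0 else ChangeKind.SHRUNK
            gt_events.append(ChangeEvent(kind, lesion.type,
                                         assign_region(lesion.centroid, geom1),
                                         baseline_lesion_id=b_id,
                                         followup_lesion_id=f_idx,
                                         area_ratio=factor))
        else:
            gt_events.append(ChangeEvent(ChangeKind.STABLE, lesion.type,
                                         assign_region(lesion.centroid, geom1),
                                         baseline_lesion_id=b_id,
                                         followup_lesion_id=f_idx,
                                         area_ratio=1.0))
        followup_lesions.append(lesion)
    for lesion, region in zip(new_lesions, new_regions):
        gt_events.append(ChangeEvent(ChangeKind.NEW, lesion.type, region,
                                     followup_lesion_id=len(followup_lesions)))
        followup_lesions.append(lesion)
    for b_id, lesion in resolved:
        gt_events.append(ChangeEvent(ChangeKind.RESOLVED, lesion.type,
                                     assign_region(lesion.centroid, geom1),
                                     baseline_lesion_id=b_id))

    followup = ImageRecord(image_id=baseline.image_id + "-followup",
                           geometry=geom1, lesions=followup_lesions,
                           eye=baseline.eye, capture_time=baseline.capture_time,
                           gradable=baseline.gradable)
    followup = apply_noise(followup, noise, rng)
    return followup, gt_events


def _place_separated(rng, t: LesionType, geometry: FundusGeometry, region: int,
                     existing: Sequence[Lesion], min_separation_dd: float,
                     attempts: int = 200) -> Lesion:
    others = [l.centroid for l in existing if l.type is t]
    for _ in range(attempts):
        lesion = _make_lesion(rng, t, geometry, region=region)
        if all(math.dist(lesion.centroid, c)
               > min_separation_dd * geometry.disc_diameter for c in others):
            return lesion
    raise InapplicableEventError(
        f"could not place a {t.value} lesion in region {region} with "
        f"{min_separation_dd} DD separation")


# ---------------------------------------------------------------------------
# Raster phantoms and the demo blob detector
# ---------------------------------------------------------------------------

_BRIGHT_TYPES = (LesionType.EXUDATE, LesionType.CWS)
_DARK_TYPES = (LesionType.MA, LesionType.HAEMORRHAGE, LesionType.BLOT_HAEMORRHAGE)

_BACKGROUND = 0.5
_DISC_INTENSITY = 0.95
_FOVEA_INTENSITY = 0.25
_VESSEL_INTENSITY = 0.3
_BRIGHT_INTENSITY = 0.9
_DARK_INTENSITY = 0.12


def _paint_disk(img: np.ndarray, centre, radius: float, value: float) -> None:
    h, w = img.shape
    cx, cy = centre
    x0, x1 = max(0, int(cx - radius - 2)), min(w, int(cx + radius + 3))
    y0, y1 = max(0, int(cy - radius - 2)), min(h, int(cy + radius + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    img[y0:y1, x0:x1][mask] = value


def render_phantom(record: ImageRecord, seed: int = 0) -> np.ndarray:
    """Render a flat-background fundus phantom (float image in [0, 1]).

    Bright disc, dark fovea patch, a few straight dark vessel segments
    radiating from the disc, bright blobs for exudates/CWS and dark blobs
    for MAs/haemorrhages.  Realism is deliberately not attempted.
    """
    geom = record.geometry
    if geom.image_width <= 0 or geom.image_height <= 0:
        raise ValueError("geometry must carry a positive canvas size")
    disc_r = geom.disc_diameter / 2.0
    fovea_r = 0.35 * geom.disc_diameter
    if math.dist(geom.disc_centre, geom.fovea_centre) <= disc_r + fovea_r:
        raise ValueError("disc and fovea footprints overlap; cannot render")
    rng = np.random.default_rng(seed)
    img = np.full((geom.image_height, geom.image_width), _BACKGROUND)
    # vessels: straight segments fanning out from the disc
    for _ in range(4):
        theta = rng.uniform(-math.pi, math.pi)
        length = rng.uniform(2.0, 3.5) * geom.disc_diameter
        steps = int(length)
        dx, dy = math.cos(theta), math.sin(theta)
        for s in range(steps):
            px = geom.disc_centre[0] + dx * s
            py = geom.disc_centre[1] + dy * s
            if math.dist((px, py), geom.fovea_centre) < fovea_r + 4:
                break
            _paint_disk(img, (px, py), 1.2, _VESSEL_INTENSITY)
    _paint_disk(img, geom.disc_centre, disc_r, _DISC_INTENSITY)
    _paint_disk(img, geom.fovea_centre, fovea_r, _FOVEA_INTENSITY)
    for lesion in record.lesions:
        radius = max(2.0, math.sqrt(lesion.area / math.pi))
        if lesion.type in _BRIGHT_TYPES:
            _paint_disk(img, lesion.centroid, radius, _BRIGHT_INTENSITY)
        elif lesion.type in _DARK_TYPES:
            _paint_disk(img, lesion.centroid, radius, _DARK_INTENSITY)
        # other lesion types have no raster signature in the phantom
    return img


def demo_detect(img: np.ndarray, image_id: str = "phantom") -> ImageRecord:
    """Recover landmarks and blob lesions from a phantom by thresholding.

    The largest bright connected component is taken as the optic disc, the
    largest compact dark component as the fovea; remaining bright blobs
    become exudates and compact dark blobs become MAs (small) or
    haemorrhages (large).  Elongated dark structures are discarded as
    vessels.
    """
    from skimage import measure

    bright = measure.label(img > 0.75)
    bright_props = sorted(measure.regionprops(bright), key=lambda p: -p.area)
    if not bright_props:
        raise ValueError("no bright structures found; not a phantom?")
    disc = bright_props[0]
    disc_centre = (disc.centroid[1], disc.centroid[0])
    disc_diameter = float(disc.equivalent_diameter_area)

    dark = measure.label(img < 0.35)
    dark_props = sorted(measure.regionprops(dark), key=lambda p: -p.area)
    compact = [p for p in dark_props if p.eccentricity < 0.9
               and (p.axis_minor_length == 0
                    or p.axis_major_length / max(p.axis_minor_length, 1e-9) < 3.0)]
    if not compact:
        raise ValueError("no fovea candidate found; not a phantom?")
    fovea = compact[0]
    fovea_centre = (fovea.centroid[1], fovea.centroid[0])
    geometry = FundusGeometry(disc_centre=disc_centre, disc_diameter=disc_diameter,
                              fovea_centre=fovea_centre,
                              image_width=img.shape[1], image_height=img.shape[0])
    lesions: list[Lesion] = []
    for p in bright_props[1:]:
        if p.area < 4:
            continue
        lesions.append(Lesion(type=LesionType.EXUDATE,
                              centroid=(p.centroid[1], p.centroid[0]),
                              area=float(p.area), confidence=1.0))
    ma_cutoff = 80.0
    for p in compact[1:]:
        if p.area < 4:
            continue
        t = LesionType.MA if p.area < ma_cutoff else LesionType.HAEMORRHAGE
        lesions.append(Lesion(type=t, centroid=(p.centroid[1], p.centroid[0]),
                              area=float(p.area), confidence=1.0))
    return ImageRecord(image_id=image_id, geometry=geometry, lesions=lesions)
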