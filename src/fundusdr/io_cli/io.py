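"""File formats: annotation JSON, ground-truth and grade-table CSV, reports.

The annotation document is a versioned JSON object holding one payload per
image (identity, landmarks, lesion list).  Reading validates the schema and
rejects unknown lesion types with diagnostics naming the offending record
and field.  Report CSV/JSON writers format floats with 6 significant digits
so identical runs produce byte-identical files; the annotation writer keeps
full float precision so write∘read is lossless.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from ..alignment_progression import ProgressionReport
from ..evaluation import EvalSummary
from ..fundus_model import Eye, FundusGeometry, ImageRecord, Lesion, LesionType
from ..grading import GradeResult

ANNOTATION_SCHEMA_VERSION = 1


class AnnotationError(ValueError):
    """Schema violation in an annotation document."""


def fmt_float(x: float) -> str:
    """6-significant-digit float formatting used in all report files."""
    return format(x, ".6g")


@dataclass
class RunConfig:
    """Bundle of run-time thresholds shared by the CLI commands."""

    scheme: str = "ICDRS"
    table_path: Optional[str] = None
    conf_threshold: float = 0.5
    match_radius_dd: float = 0.25
    area_deadband: float = 0.2
    maculopathy_radius_dd: float = 1.0
    ci_method: str = "wilson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf_threshold <= 1.0):
            raise ValueError("conf_threshold must be in [0, 1]")
        if self.match_radius_dd <= 0 or self.area_deadband < 0:
            raise ValueError("match_radius_dd must be > 0 and area_deadband >= 0")
        if self.ci_method not in ("wilson", "clopper"):
            raise ValueError("ci_method must be 'wilson' or 'clopper'")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Annotation JSON
# ---------------------------------------------------------------------------

def _require(payload: Mapping, key: str, where: str):
    if key not in payload:
        raise AnnotationError(f"{where}: missing required field {key!r}")
    return payload[key]


def _parse_point(value, where: str) -> tuple[float, float]:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise AnnotationError(f"{where}: expected a [x, y] pair, got {value!r}")
    return (float(value[0]), float(value[1]))


def _parse_record(payload: Mapping, index: int, allow_outside: bool) -> ImageRecord:
    where = f"images[{index}]"
    image_id = _require(payload, "image_id", where)
    gpay = _require(payload, "geometry", where)
    gw = f"{where}.geometry"
    geometry = FundusGeometry(
        disc_centre=_parse_point(_require(gpay, "disc_centre", gw), f"{gw}.disc_centre"),
        disc_diameter=float(_require(gpay, "disc_diameter", gw)),
        fovea_centre=_parse_point(_require(gpay, "fovea_centre", gw), f"{gw}.fovea_centre"),
        image_width=int(gpay.get("image_width", 0)),
        image_height=int(gpay.get("image_height", 0)),
    )
    lesions = []
    for j, lpay in enumerate(payload.get("lesions", [])):
        lw = f"{where}.lesions[{j}]"
        try:
            ltype = LesionType.parse(_require(lpay, "type", lw))
        except ValueError as exc:
            raise AnnotationError(f"{lw}.type: {exc}") from None
        centroid = _parse_point(_require(lpay, "centroid", lw), f"{lw}.centroid")
        if not allow_outside and geometry.image_width > 0 and geometry.image_height > 0:
            x, y = centroid
            if not (0 <= x < geometry.image_width and 0 <= y < geometry.image_height):
                raise AnnotationError(
                    f"{lw}.centroid: ({x}, {y}) lies outside the "
                    f"{geometry.image_width}x{geometry.image_height} image "
                    f"(pass allow_outside=True to accept)")
        try:
            lesions.append(Lesion(type=ltype, centroid=centroid,
                                  area=float(_require(lpay, "area", lw)),
                                  confidence=float(lpay.get("confidence", 1.0))))
        except ValueError as exc:
            raise AnnotationError(f"{lw}: {exc}") from None
    eye_label = payload.get("eye", "UNKNOWN")
    try:
        eye = Eye(eye_label)
    except ValueError:
        raise AnnotationError(f"{where}.eye: unknown eye {eye_label!r}") from None
    return ImageRecord(
        image_id=image_id,
        geometry=geometry,
        lesions=lesions,
        eye=eye,
        capture_time=payload.get("capture_time", ""),
        gradable=bool(payload.get("gradable", True)),
    )


def read_annotations(path, allow_outside: bool = False) -> list[ImageRecord]:
    """Read and validate an annotation document."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: malformed JSON: {exc}") from None
    version = doc.get("schema_version")
    if version != ANNOTATION_SCHEMA_VERSION:
        raise AnnotationError(
            f"{path}: unsupported schema_version {version!r} "
            f"(expected {ANNOTATION_SCHEMA_VERSION})")
    images = doc.get("images")
    if not isinstance(images, list):
        raise AnnotationError(f"{path}: 'images' must be a list")
    return [_parse_record(p, i, allow_outside) for i, p in enumerate(images)]


def _record_payload(record: ImageRecord) -> dict:
    return {
        "image_id": record.image_id,
        "eye": record.eye.value,
        "capture_time": record.capture_time,
        "gradable": record.gradable,
        "geometry": {
            "disc_centre": list(record.geometry.disc_centre),
            "disc_diameter": record.geometry.disc_diameter,
            "fovea_centre": list(record.geometry.fovea_centre),
            "image_width": record.geometry.image_width,
            "image_height": record.geometry.image_height,
        },
        "lesions": [
            {"type": l.type.value, "centroid": list(l.centroid),
             "area": l.area, "confidence": l.confidence}
            for l in record.lesions
        ],
    }


def write_annotations(records: Sequence[ImageRecord], path) -> None:
    doc = {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "images": [_record_payload(r) for r in records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Mask PNG sidecars
# ---------------------------------------------------------------------------

def mask_to_lesions(path, lesion_type: LesionType,
                    confidence: float = 1.0) -> list[Lesion]:
    """Convert a binary lesion mask image into centroid+area lesions.

    Non-zero pixels are foreground; each 8-connected component becomes one
    lesion of *lesion_type*.
    """
    import numpy as np
    from PIL import Image
    from scipy import ndimage

    mask = np.asarray(Image.open(path).convert("L")) > 0
    labelled, n = ndimage.label(mask, structure=np.ones((3, 3)))
    lesions = []
    for (cy, cx), area in zip(
            ndimage.center_of_mass(mask, labelled, range(1, n + 1)),
            ndimage.sum_labels(mask, labelled, range(1, n + 1))):
        lesions.append(Lesion(type=lesion_type, centroid=(float(cx), float(cy)),
                              area=float(area), confidence=confidence))
    return lesions


# ---------------------------------------------------------------------------
# Tables and reports
# ---------------------------------------------------------------------------

GT_COLUMNS = ("image_id", "level", "maculopathy")


def write_gt_table(rows: Sequence[tuple[str, str, bool]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GT_COLUMNS)
        for image_id, level, mac in rows:
            writer.writerow([image_id, level, str(bool(mac)).lower()])


def read_gt_table(path) -> dict[str, tuple[str, bool]]:
    table: dict[str, tuple[str, bool]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(GT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationError(f"{path}: ground-truth CSV missing columns {sorted(missing)}")
        for row in reader:
            table[row["image_id"]] = (row["level"], row["maculopathy"].lower() == "true")
    return table


GRADE_COLUMNS = ("image_id", "icdrs_level", "nsc_level", "maculopathy",
                 "referable", "evidence")


def write_grade_table(rows: Sequence[Mapping], path) -> None:
    """One row per image: both schemes' levels, the DMO flag, referability
    under the selected scheme, and the firing rule with its lesion ids."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GRADE_COLUMNS)
        for row in rows:
            writer.writerow([row[c] for c in GRADE_COLUMNS])


def read_grade_table(path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(GRADE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationError(f"{path}: grade table missing columns {sorted(missing)}")
        return list(reader)


def evidence_string(result: GradeResult) -> str:
    parts = []
    for rule, ids in result.evidence:
        id_str = ":".join(str(i) for i in ids)
        parts.append(f"{rule}[{id_str}]")
    return ";".join(parts)


def _metric_cells(metric) -> list[str]:
    if metric is None:
        return ["", "", ""]
    return [fmt_float(metric.value), fmt_float(metric.ci_low), fmt_float(metric.ci_high)]


EVAL_COLUMNS = ("task", "tp", "tn", "fp", "fn",
                "sensitivity", "sensitivity_ci_low", "sensitivity_ci_high",
                "specificity", "specificity_ci_low", "specificity_ci_high",
                "ppv", "ppv_ci_low", "ppv_ci_high",
                "npv", "npv_ci_low", "npv_ci_high",
                "accuracy", "accuracy_ci_low", "accuracy_ci_high",
                "kappa_qw", "auc")


def write_eval_report(summaries: Sequence[EvalSummary], csv_path, json_path=None) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVAL_COLUMNS)
        for s in summaries:
            row = [s.task, s.tp, s.tn, s.fp, s.fn]
            for metric in (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy):
                row.extend(_metric_cells(metric))
            row.append(fmt_float(s.kappa_qw) if s.kappa_qw is not None else "")
            row.append(fmt_float(s.auc) if s.auc is not None else "")
            writer.writerow(row)
    if json_path is not None:
        payload = [_eval_json(s) for s in summaries]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _eval_json(s: EvalSummary) -> dict:
    def metric_obj(m):
        if m is None:
            return None
        return {"value": round(m.value, 6), "ci_low": round(m.ci_low, 6),
                "ci_high": round(m.ci_high, 6)}

    return {
        "task": s.task,
        "counts": {"tp": s.tp, "tn": s.tn, "fp": s.fp, "fn": s.fn},
        "sensitivity": metric_obj(s.sensitivity),
        "specificity": metric_obj(s.specificity),
        "ppv": metric_obj(s.ppv),
        "npv": metric_obj(s.npv),
        "accuracy": metric_obj(s.accuracy),
        "ci_method": s.ci_method,
        "kappa_qw": None if s.kappa_qw is None else round(s.kappa_qw, 6),
        "auc": None if s.auc is None else round(s.auc, 6),
    }


EVENT_COLUMNS = ("kind", "lesion_type", "region", "baseline_lesion_id",
                 "followup_lesion_id", "area_ratio")


def write_progression_report(report: ProgressionReport, json_path, csv_path) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in report.events:
            writer.writerow([
                ev.kind.value, ev.lesion_type.value, ev.region,
                "" if ev.baseline_lesion_id is None else ev.baseline_lesion_id,
                "" if ev.followup_lesion_id is None else ev.followup_lesion_id,
                "" if ev.area_ratio is None else fmt_float(ev.area_ratio),
            ])
    payload = {
        "transform": {
            "scale": round(report.transform.scale, 9),
            "rotation": round(report.transform.rotation, 9),
            "translation": [round(v, 6) for v in report.transform.translation],
        },
        "baseline_grade": {"scheme": report.baseline_grade.scheme,
                           "level": report.baseline_grade.level,
                           "dmo": report.baseline_grade.dmo,
                           "referable": report.baseline_grade.referable},
        "followup_grade": {"scheme": report.followup_grade.scheme,
                           "level": report.followup_grade.level,
                           "dmo": report.followup_grade.dmo,
                           "referable": report.followup_grade.referable},
        "grade_delta": report.grade_delta,
        "event_counts": {k.value: v for k, v in report.kind_counts.items()},
        "region_event_counts": {
            str(r): {k.value: v for k, v in kinds.items() if v}
            for r, kinds in report.region_kind_counts.items()},
        "type_event_counts": {
            t.value: {k.value: v for k, v in kinds.items() if v}
            for t, kinds in report.type_kind_counts.items()},
        "n_events": len(report.events),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
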