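from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ..fundus_model import (
    DR_LESION_TYPES,
    ImageRecord,
    LesionType,
    assign_quadrant,
    assign_region,
    distance_dd,
)

__all__ = [
    "LesionSummary",
    "DecisionTable",
    "GradeResult",
    "ReferabilityPolicy",
    "summarise",
    "load_table",
    "default_table",
    "load_policy",
    "default_policy",
    "grade",
    "grade_icdrs",
    "grade_nsc",
    "assess_maculopathy",
    "is_referable",
    "featurise",
    "FEATURE_LENGTH",
    "EnsembleGrader",
    "train_ensemble_grader",
    "predict_ensemble",
]

DEFAULT_CONF_THRESHOLD = 0.5
DEFAULT_MACULOPATHY_RADIUS_DD = 1.0


class TableConfigError(ValueError):
    """Raised for a malformed decision table or referability policy."""


# ---------------------------------------------------------------------------
# Lesion summary
# ---------------------------------------------------------------------------

@dataclass
class LesionSummary:
    """Confidence-filtered per-type statistics of one image's lesion set.

    Artefacts and lesions below the confidence threshold are excluded from
    every count.  ``min_fovea_dd`` is +inf for absent types.  ``lesion_ids``
    holds indices into the originating record's lesion list (evidence).
    """

    counts: dict[LesionType, int]
    region_counts: dict[LesionType, list[int]]
    quadrant_counts: dict[LesionType, list[int]]
    areas: dict[LesionType, float]
    min_fovea_dd: dict[LesionType, float]
    lesion_ids: dict[LesionType, list[int]]
    conf_threshold: float = DEFAULT_CONF_THRESHOLD

    def count(self, t: LesionType) -> int:
        return self.counts.get(t, 0)

    def present_types(self) -> list[LesionType]:
        return [t for t in DR_LESION_TYPES if self.counts.get(t, 0) > 0]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarise(record: ImageRecord, conf_threshold: float = DEFAULT_CONF_THRESHOLD) -> LesionSummary:
    """Aggregate a record's lesions into the counts the decision tables read.

    Lesions with confidence strictly below *conf_threshold* and all
    ``ARTEFACT`` lesions are excluded.
    """
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError(f"conf_threshold must be in [0, 1], got {conf_threshold}")
    geom = record.geometry
    counts: dict[LesionType, int] = {t: 0 for t in DR_LESION_TYPES}
    region_counts = {t: [0] * 5 for t in DR_LESION_TYPES}
    quadrant_counts = {t: [0] * 4 for t in DR_LESION_TYPES}
    areas = {t: 0.0 for t in DR_LESION_TYPES}
    min_dd = {t: math.inf for t in DR_LESION_TYPES}
    ids: dict[LesionType, list[int]] = {t: [] for t in DR_LESION_TYPES}
    for i, lesion in enumerate(record.lesions):
        if lesion.type is LesionType.ARTEFACT or lesion.confidence < conf_threshold:
            continue
        t = lesion.type
        counts[t] += 1
        region_counts[t][assign_region(lesion.centroid, geom) - 1] += 1
        quadrant_counts[t][assign_quadrant(lesion.centroid, geom) - 1] += 1
        areas[t] += lesion.area
        min_dd[t] = min(min_dd[t], distance_dd(lesion.centroid, geom))
        ids[t].append(i)
    return LesionSummary(counts, region_counts, quadrant_counts, areas, min_dd, ids,
                         conf_threshold=conf_threshold)


# ---------------------------------------------------------------------------
# Decision tables
# ---------------------------------------------------------------------------

def _condition_types(cond: Mapping) -> list[LesionType]:
    if "present" in cond:
        names = cond["present"]
    elif "lesions" in cond:
        names = cond["lesions"]
    elif "lesion" in cond:
        names = [cond["lesion"]]
    else:
        raise TableConfigError(f"condition references no lesion type: {cond!r}")
    types = [LesionType.parse(n) for n in names]
    if LesionType.ARTEFACT in types:
        raise TableConfigError("ARTEFACT may not appear in a decision table")
    return types


def _eval_condition(cond: Mapping, summary: LesionSummary) -> bool:
    types = _condition_types(cond)
    if "present" in cond:
        return any(summary.count(t) > 0 for t in types)
    if "min_per_quadrant" in cond:
        per_quadrant = [0, 0, 0, 0]
        for t in types:
            for q in range(4):
                per_quadrant[q] += summary.quadrant_counts[t][q]
        need_q = int(cond.get("min_quadrants", 4))
        hits = sum(1 for c in per_quadrant if c >= int(cond["min_per_quadrant"]))
        return hits >= need_q
    if "min_quadrants_present" in cond:
        per_quadrant = [0, 0, 0, 0]
        for t in types:
            for q in range(4):
                per_quadrant[q] += summary.quadrant_counts[t][q]
        return sum(1 for c in per_quadrant if c > 0) >= int(cond["min_quadrants_present"])
    if "min_count" in cond:
        return sum(summary.count(t) for t in types) >= int(cond["min_count"])
    if "min_area" in cond:
        return sum(summary.areas[t] for t in types) >= float(cond["min_area"])
    if "max_dd" in cond:
        return any(summary.min_fovea_dd[t] <= float(cond["max_dd"]) for t in types)
    raise TableConfigError(f"condition has no recognised predicate: {cond!r}")


@dataclass(frozen=True)
class DecisionTable:
    """Ordered severity rules for one grading scheme.

    Rules are evaluated from the highest level down; the first rule whose
    condition holds assigns the level.  The lowest level must be the default
    (empty) rule, which the empty summary and only the empty summary of any
    higher predicate satisfies.
    """

    scheme: str
    levels: tuple[str, ...]
    rules: tuple[Mapping, ...]
    level_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise TableConfigError("a table needs at least two levels")
        rule_levels = [r["level"] for r in self.rules]
        if sorted(rule_levels, key=self.level_index, reverse=True) != rule_levels:
            raise TableConfigError("rules must be ordered highest severity first")
        last = self.rules[-1]
        if not last.get("default") or last["level"] != self.levels[0]:
            raise TableConfigError("the last rule must be the default lowest level")
        for rule in self.rules[:-1]:
            conds = rule.get("any", [])
            if not conds:
                raise TableConfigError(f"non-default rule for level {rule['level']} has no conditions")
            for cond in conds:
                _condition_types(cond)  # validates lesion labels eagerly

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise TableConfigError(f"level {level!r} not in scheme {self.scheme}") from None

    def evaluate(self, summary: LesionSummary) -> tuple[str, Mapping, list[int]]:
        """Return (level, firing rule, supporting lesion ids)."""
        for rule in self.rules[:-1]:
            for cond in rule["any"]:
                if _eval_condition(cond, summary):
                    support: list[int] = []
                    for t in _condition_types(cond):
                        support.extend(summary.lesion_ids[t])
                    return rule["level"], rule, sorted(support)
        return self.rules[-1]["level"], self.rules[-1], []


def _table_from_dict(doc: Mapping) -> DecisionTable:
    try:
        return DecisionTable(
            scheme=doc["scheme"],
            levels=tuple(doc["levels"]),
            rules=tuple(doc["rules"]),
            level_names=doc.get("level_names", {}),
        )
    except KeyError as exc:
        raise TableConfigError(f"decision table missing field {exc}") from None


def load_table(path) -> DecisionTable:
    """Load a decision table from a JSON file."""
    with open(path) as fh:
        return _table_from_dict(json.load(fh))


def default_table(scheme: str) -> DecisionTable:
    """The shipped table for ``"ICDRS"`` or ``"NSC"``."""
    name = scheme.lower()
    if name not in ("icdrs", "nsc"):
        raise TableConfigError(f"no default table for scheme {scheme!r}")
    ref = resources.files(__package__).joinpath(f"tables/{name}.json")
    return _table_from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Referability policy and maculopathy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferabilityPolicy:
    """Scheme → (referable levels, whether maculopathy alone refers)."""

    referable_levels: Mapping[str, frozenset]
    dmo_referable: Mapping[str, bool]

    def decide(self, scheme: str, level: str, dmo: bool) -> bool:
        if scheme not in self.referable_levels:
            raise TableConfigError(f"no referability policy for scheme {scheme!r}")
        if dmo and self.dmo_referable[scheme]:
            return True
        return level in self.referable_levels[scheme]


def _policy_from_dict(doc: Mapping) -> ReferabilityPolicy:
    return ReferabilityPolicy(
        referable_levels={s: frozenset(v["referable_levels"]) for s, v in doc.items()},
        dmo_referable={s: bool(v.get("dmo_referable", True)) for s, v in doc.items()},
    )


def load_policy(path) -> ReferabilityPolicy:
    with open(path) as fh:
        return _policy_from_dict(json.load(fh))


def default_policy() -> ReferabilityPolicy:
    ref = resources.files(__package__).joinpath("tables/referability.json")
    return _policy_from_dict(json.loads(ref.read_text()))


def assess_maculopathy(summary: LesionSummary,
                       radius_dd: float = DEFAULT_MACULOPATHY_RADIUS_DD) -> bool:
    """Surrogate macular-oedema marker: any exudate within *radius_dd* of the fovea."""
    return summary.min_fovea_dd[LesionType.EXUDATE] <= radius_dd


def is_referable(scheme: str, level: str, dmo: bool,
                 policy: Optional[ReferabilityPolicy] = None) -> bool:
    """Deterministic referability lookup under *policy* (default shipped policy)."""
    if policy is None:
        policy = default_policy()
    return policy.decide(scheme, level, dmo)


# ---------------------------------------------------------------------------
# Grading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeResult:
    """Severity call for one image under one scheme."""

    scheme: str
    level: str
    level_index: int
    dmo: bool
    referable: bool
    evidence: tuple = ()
    probabilities: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.probabilities is not None:
            total = sum(self.probabilities.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1, got {total}")


def grade(summary: LesionSummary, table: DecisionTable,
          policy: Optional[ReferabilityPolicy] = None,
          maculopathy_radius_dd: float = DEFAULT_MACULOPATHY_RADIUS_DD) -> GradeResult:
    """Grade a lesion summary with a decision table.

    DMO is assessed from exudate proximity to the fovea and combined with
    the level through the referability policy.
    """
    level, rule, support = table.evaluate(summary)
    dmo = assess_maculopathy(summary, maculopathy_radius_dd)
    referable = is_referable(table.scheme, level, dmo, policy)
    evidence = ((_describe_rule(table, rule), tuple(support)),)
    return GradeResult(
        scheme=table.scheme,
        level=level,
        level_index=table.level_index(level),
        dmo=dmo,
        referable=referable,
        evidence=evidence,
    )


def _describe_rule(table: DecisionTable, rule: Mapping) -> str:
    name = table.level_names.get(rule["level"], "")
    label = f"{rule['level']} ({name})" if name else rule["level"]
    return f"{table.scheme} level {label}"


def grade_icdrs(summary: LesionSummary, table: Optional[DecisionTable] = None,
                **kwargs) -> GradeResult:
    table = table if table is not None else default_table("ICDRS")
    if table.scheme != "ICDRS":
        raise TableConfigError(f"expected an ICDRS table, got {table.scheme}")
    return grade(summary, table, **kwargs)


def grade_nsc(summary: LesionSummary, table: Optional[DecisionTable] = None,
              **kwargs) -> GradeResult:
    table = table if table is not None else default_table("NSC")
    if table.scheme != "NSC":
        raise TableConfigError(f"expected an NSC table, got {table.scheme}")
    return grade(summary, table, **kwargs)


# ---------------------------------------------------------------------------
# Feature vectors and the ensemble grader
# ---------------------------------------------------------------------------

#: slots per lesion type: total count, log1p(total area), 5 region counts
_SLOTS_PER_TYPE = 7
FEATURE_LENGTH = len(DR_LESION_TYPES) * _SLOTS_PER_TYPE


def featurise(summary: LesionSummary) -> np.ndarray:
    """Fixed-length feature vector of a summary.

    Ordering is stable: for each gradeable lesion type in enumeration order,
    (total count, log(1 + total area), region-1..5 counts).
    """
    vec = np.zeros(FEATURE_LENGTH)
    for i, t in enumerate(DR_LESION_TYPES):
        base = i * _SLOTS_PER_TYPE
        vec[base] = summary.counts[t]
        vec[base + 1] = math.log1p(summary.areas[t])
        vec[base + 2:base + 7] = summary.region_counts[t]
    return vec


@dataclass
class EnsembleGrader:
    """Trained bagged-tree grader producing per-level probabilities."""

    scheme: str
    levels: tuple[str, ...]
    classifier: RandomForestClassifier


def train_ensemble_grader(features: Sequence[Sequence[float]],
                          labels: Sequence[str],
                          scheme: str,
                          seed: int,
                          n_estimators: int = 100) -> EnsembleGrader:
    """Fit a seeded random-forest on (feature vector, level label) pairs."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.shape[0] == 0:
        raise ValueError("cohort is empty")
    if len(set(y)) < 2:
        raise ValueError("cohort must contain at least two distinct levels")
    table = default_table(scheme)
    for lab in set(y):
        table.level_index(lab)  # reject labels outside the scheme
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return EnsembleGrader(scheme=scheme, levels=table.levels, classifier=clf)


def predict_ensemble(handle: EnsembleGrader, vector: Sequence[float],
                     policy: Optional[ReferabilityPolicy] = None) -> GradeResult:
    """Predict per-level probabilities; argmax ties break toward lower severity."""
    X = np.asarray(vector, dtype=float).reshape(1, -1)
    raw = handle.classifier.predict_proba(X)[0]
    probs = {level: 0.0 for level in handle.levels}
    for cls, p in zip(handle.classifier.classes_, raw):
        probs[cls] = float(p)
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    # first max over severity-ordered levels → conservative tie-break
    best = max(handle.levels, key=lambda lv: (probs[lv], -handle.levels.index(lv)))
    idx = handle.levels.index(best)
    referable = is_referable(handle.scheme, best, False, policy)
    return GradeResult(
        scheme=handle.scheme,
        level=best,
        level_index=idx,
        dmo=False,
        referable=referable,
        evidence=(("ensemble argmax", ()),),
        probabilities=probs,
    )
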