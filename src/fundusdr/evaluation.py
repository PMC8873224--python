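"""Screening-evaluation machinery.

Implements the lesion-conditioned confusion outcomes (a detection that
overshoots the ground-truth severity is a false positive even when the
image is positive, and an image where only lesions of the correct
non-referable severity are found counts as a true negative), plus
quadratic weighted kappa, sensitivity/specificity/PPV/NPV with 95%
confidence intervals, ROC analysis with dual operating-point selection,
prevalence subsampling and the human-workload-reduction figure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Outcome",
    "BinaryTask",
    "EvalSummary",
    "Metric",
    "classify_outcome",
    "classify_dmo_outcome",
    "summarise_eval",
    "quadratic_weighted_kappa",
    "roc_curve",
    "auc",
    "OperatingPoint",
    "select_operating_point",
    "subsample_prevalence",
    "workload_reduction",
]


class Outcome(enum.Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


TASK_NAMES = ("DR_VS_NONDR", "REFERABLE", "PDR_VS_NONPDR", "DMO")

# minimum positive level index per level-based task, per scheme
_TASK_THRESHOLDS = {
    "ICDRS": {"DR_VS_NONDR": 1, "REFERABLE": 2, "PDR_VS_NONPDR": 4},
    "NSC": {"DR_VS_NONDR": 1, "REFERABLE": 2, "PDR_VS_NONPDR": 3},
}


@dataclass(frozen=True)
class BinaryTask:
    """A binary screening question over a scheme's ordered severity levels.

    The positive set is upward-closed: every level at or above the task
    threshold is positive.  The DMO task is driven by the maculopathy flag
    instead of the level.
    """

    name: str
    scheme: str
    positive_threshold: Optional[int]  # level index; None for DMO

    @classmethod
    def for_scheme(cls, name: str, scheme: str) -> "BinaryTask":
        if name == "DMO":
            return cls(name=name, scheme=scheme, positive_threshold=None)
        try:
            thr = _TASK_THRESHOLDS[scheme][name]
        except KeyError:
            raise ValueError(f"unknown task {name!r} for scheme {scheme!r}") from None
        return cls(name=name, scheme=scheme, positive_threshold=thr)

    def is_positive(self, level_index: int) -> bool:
        if self.positive_threshold is None:
            raise ValueError("DMO task positivity is flag-based, not level-based")
        return level_index >= self.positive_threshold


def classify_outcome(predicted_index: int, gt_index: int, task: BinaryTask,
                     conventional: bool = False) -> Outcome:
    """Assign TP/TN/FP/FN for one image on a level-based task.

    Default mode is the lesion-conditioned rule set: a prediction strictly
    above ground truth is FP regardless of the ground truth's own
    positivity; with a positive ground truth, a positive prediction at or
    below it is TP and a negative one is FN; a non-positive image with no
    overshoot is TN.  ``conventional=True`` instead thresholds both sides
    and fills the ordinary confusion matrix.
    """
    p_pos = task.is_positive(predicted_index)
    g_pos = task.is_positive(gt_index)
    if conventional:
        if g_pos:
            return Outcome.TP if p_pos else Outcome.FN
        return Outcome.FP if p_pos else Outcome.TN
    if predicted_index > gt_index:
        return Outcome.FP
    if g_pos:
        return Outcome.TP if p_pos else Outcome.FN
    return Outcome.TN


def classify_dmo_outcome(predicted_dmo: bool, gt_dmo: bool) -> Outcome:
    if gt_dmo:
        return Outcome.TP if predicted_dmo else Outcome.FN
    return Outcome.FP if predicted_dmo else Outcome.TN


# ---------------------------------------------------------------------------
# Summary metrics with confidence intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metric:
    """A proportion with its 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


def _proportion(num: int, den: int, ci_method: str) -> Optional[Metric]:
    if den == 0:
        return None
    method = {"wilson": "wilson", "clopper": "beta"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown CI method {ci_method!r}; use 'wilson' or 'clopper'")
    lo, hi = proportion_confint(num, den, alpha=0.05, method=method)
    return Metric(value=num / den, ci_low=float(lo), ci_high=float(hi),
                  numerator=num, denominator=den)


@dataclass
class EvalSummary:
    """Confusion counts and derived screening metrics for one binary task."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: Optional[Metric]
    specificity: Optional[Metric]
    ppv: Optional[Metric]
    npv: Optional[Metric]
    accuracy: Optional[Metric]
    ci_method: str = "wilson"
    kappa_qw: Optional[float] = None
    auc: Optional[float] = None
    task: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def summarise_eval(outcomes: Sequence[Outcome], ci_method: str = "wilson",
                   task: str = "") -> EvalSummary:
    """Counts, point metrics and 95% CIs from a list of outcome labels.

    Metrics whose denominator is empty are reported as absent (None), never
    as zero.
    """
    if not outcomes:
        raise ValueError("outcome list is empty")
    tp = sum(1 for o in outcomes if o is Outcome.TP)
    tn = sum(1 for o in outcomes if o is Outcome.TN)
    fp = sum(1 for o in outcomes if o is Outcome.FP)
    fn = sum(1 for o in outcomes if o is Outcome.FN)
    return EvalSummary(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=_proportion(tp, tp + fn, ci_method),
        specificity=_proportion(tn, tn + fp, ci_method),
        ppv=_proportion(tp, tp + fp, ci_method),
        npv=_proportion(tn, tn + fn, ci_method),
        accuracy=_proportion(tp + tn, tp + tn + fp + fn, ci_method),
        ci_method=ci_method,
        task=task,
    )


def workload_reduction(outcomes: Sequence[Outcome]) -> float:
    """Fraction of images cleared without human review when only positive
    returns are re-graded by a human: (TN + FN) / total."""
    if not outcomes:
        raise ValueError("outcome list is empty")
    cleared = sum(1 for o in outcomes if o in (Outcome.TN, Outcome.FN))
    return cleared / len(outcomes)


# ---------------------------------------------------------------------------
# Quadratic weighted kappa
# ---------------------------------------------------------------------------

def quadratic_weighted_kappa(rater_a: Sequence[int], rater_b: Sequence[int],
                             k: int) -> float:
    """Chance-corrected ordinal agreement with squared-distance weights.

    κ = 1 − Σ w_ij O_ij / Σ w_ij E_ij with w_ij = (i−j)²/(k−1)², O the
    observed k×k contingency table and E the outer product of the two
    marginals scaled to n.  Raises when the chance-disagreement denominator
    vanishes (both raters constant and identical), where κ is undefined.
    """
    a = np.asarray(rater_a, dtype=int)
    b = np.asarray(rater_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired ratings")
    if a.min() < 0 or b.min() < 0 or a.max() >= k or b.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    observed = np.zeros((k, k))
    np.add.at(observed, (a, b), 1.0)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    idx = np.arange(k)
    weights = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    denom = float((weights * expected).sum())
    if denom == 0.0:
        raise ValueError("quadratic weighted kappa undefined: no chance disagreement")
    return 1.0 - float((weights * observed).sum()) / denom


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def roc_curve(scores: Sequence[float], labels: Sequence[bool],
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points from continuous scores (higher score = more positive).

    Thresholds sweep the unique scores in descending order; a point's
    classifier calls positive every sample with score >= threshold.
    Returns (fpr, tpr, thresholds) with a leading (0, 0) point at
    threshold +inf; both coordinate arrays are monotone non-decreasing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last index of every tied score block
    last_of_block = np.r_[np.diff(s_sorted) != 0, True]
    thresholds = np.r_[np.inf, s_sorted[last_of_block]]
    tpr = np.r_[0.0, tps[last_of_block] / n_pos]
    fpr = np.r_[0.0, fps[last_of_block] / n_neg]
    return fpr, tpr, thresholds


def auc(fpr: Sequence[float], tpr: Sequence[float]) -> float:
    """Area under an ROC curve by the trapezoidal rule."""
    return float(np.trapezoid(np.asarray(tpr, dtype=float),
                              np.asarray(fpr, dtype=float)))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    feasible: bool


def select_operating_point(scores: Sequence[float], labels: Sequence[bool],
                           mode: str, floor: float) -> OperatingPoint:
    """Pick a threshold for a high-sensitivity or high-specificity regime.

    ``mode="HIGH_SENSITIVITY"``: maximise specificity subject to
    sensitivity >= floor.  ``mode="HIGH_SPECIFICITY"``: maximise sensitivity
    subject to specificity >= floor.  If no threshold satisfies the floor,
    the point closest to it is returned with ``feasible=False``.
    """
    if not (0.0 < floor < 1.0):
        raise ValueError(f"floor must be in (0, 1), got {floor}")
    if mode not in ("HIGH_SENSITIVITY", "HIGH_SPECIFICITY"):
        raise ValueError(f"unknown mode {mode!r}")
    fpr, tpr, thresholds = roc_curve(scores, labels)
    sens = tpr
    spec = 1.0 - fpr
    if mode == "HIGH_SENSITIVITY":
        constraint, objective = sens, spec
    else:
        constraint, objective = spec, sens
    ok = constraint >= floor
    if ok.any():
        cand = np.flatnonzero(ok)
        best = cand[np.argmax(objective[cand])]
        feasible = True
    else:
        best = int(np.argmax(constraint))
        feasible = False
    thr = float(thresholds[best])
    return OperatingPoint(
        threshold=thr,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        **_predictive_values(np.asarray(scores, float), np.asarray(labels, bool), thr),
        feasible=feasible,
    )


def _predictive_values(s: np.ndarray, y: np.ndarray, thr: float) -> dict:
    called = s >= thr
    tp = int((called & y).sum())
    fp = int((called & ~y).sum())
    tn = int((~called & ~y).sum())
    fn = int((~called & y).sum())
    return {
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
    }


# ---------------------------------------------------------------------------
# Prevalence subsampling
# ---------------------------------------------------------------------------

def subsample_prevalence(items: Sequence, labels: Sequence[bool],
                         target_prevalence: float, seed: int,
                         ) -> tuple[list, list]:
    """Downsample positives (keeping all negatives) to a target prevalence.

    The number of retained positives is chosen so the realised positive
    fraction is within one record of the target; selection is uniform at
    random and fully determined by *seed*.  Original relative order is
    preserved.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError(f"target prevalence must be in (0, 1), got {target_prevalence}")
    labels = [bool(l) for l in labels]
    if len(items) != len(labels):
        raise ValueError("items and labels differ in length")
    pos_idx = [i for i, l in enumerate(labels) if l]
    n_pos = len(pos_idx)
    n_neg = len(labels) - n_pos
    if n_neg == 0:
        raise ValueError("cannot reach a fractional prevalence with no negatives")
    keep = round(target_prevalence * n_neg / (1.0 - target_prevalence))
    if keep > n_pos:
        raise ValueError(
            f"target prevalence {target_prevalence} unreachable by downsampling: "
            f"needs {keep} positives, only {n_pos} available")
    if keep == n_pos:
        return list(items), list(labels)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n_pos, size=keep, replace=False).tolist())
    kept_pos = {pos_idx[j] for j in chosen}
    kept = [i for i, l in enumerate(labels) if not l or i in kept_pos]
    return [items[i] for i in kept], [labels[i] for i in kept]
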