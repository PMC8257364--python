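"""Diagnostic-accuracy evaluation.

Confusion-matrix rates, ROC sweep over the readout threshold, upper convex
hull and AUC, balanced operating-point selection, clinical utility indices
(CUI+ = sensitivity x PPV for rule-in value, CUI- = specificity x NPV for
rule-out value, graded excellent/good/satisfactory/poor at 0.81/0.64/0.49),
single-scale optimum cut-offs, and reconstruction of integer confusion
matrices from rates printed at fixed precision (used to re-derive accuracy
and CUI cells of published result tables, e.g. physician-rating rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import Cohort, CohortError, SubjectRecord
from .cpn import CPNModel


class EvaluationError(ValueError):
    """Undefined rate or invalid evaluation input."""


# ---------------------------------------------------------------------------
# Confusion matrix and scalar rates


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/TN/FP counts; positives are MCI."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        raise EvaluationError(f"{name} undefined: zero denominator")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """True positive rate tp / (tp + fn)."""
    return _rate(cm.tp, cm.n_pos, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """True negative rate tn / (tn + fp)."""
    return _rate(cm.tn, cm.n_neg, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    return _rate(cm.tp + cm.tn, cm.total, "accuracy")


def ppv(cm: ConfusionMatrix) -> float:
    """Positive predictive value tp / (tp + fp)."""
    return _rate(cm.tp, cm.tp + cm.fp, "ppv")


def npv(cm: ConfusionMatrix) -> float:
    """Negative predictive value tn / (tn + fn)."""
    return _rate(cm.tn, cm.tn + cm.fn, "npv")


def confusion_matrix(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    lab = np.asarray(labels, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    if lab.shape != pred.shape:
        raise EvaluationError("labels and predictions differ in length")
    return ConfusionMatrix(
        tp=int(((lab == 1) & (pred == 1)).sum()),
        fn=int(((lab == 1) & (pred == 0)).sum()),
        tn=int(((lab == 0) & (pred == 0)).sum()),
        fp=int(((lab == 0) & (pred == 1)).sum()),
    )


def confusion_from_rates(
    sen: float, spc: float, n_pos: int, n_neg: int, decimals: int = 4
) -> ConfusionMatrix:
    """Reconstruct integer TP/FN/TN/FP from rates printed at fixed precision.

    ``sen`` and ``spc`` are fractions (0.9000 for a printed "90.00%");
    ``decimals`` is the printed precision on the fraction scale (4 for
    two-decimal percentages).  TP and TN are the nearest integers to
    sen x n_pos and spc x n_neg (half away from zero); if re-deriving the
    rates from those counts disagrees with the inputs by more than about half
    an ulp of the printed precision the inputs are not integer-consistent and
    an error names the nearest consistent counts.  The tolerance is 0.55 ulp
    rather than exactly 0.5 because published tables are sometimes
    double-rounded (three decimals first, then two), which shifts a boundary
    case by up to half an ulp of the intermediate precision.
    """
    if not (0 <= sen <= 1 and 0 <= spc <= 1):
        raise EvaluationError("rates must lie in [0, 1]")
    tp = int(math.floor(sen * n_pos + 0.5))
    tn = int(math.floor(spc * n_neg + 0.5))
    cm = ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
    tol = 0.55 * 10.0 ** (-decimals)
    bad = []
    if abs(sensitivity(cm) - sen) > tol:
        bad.append(f"sensitivity: nearest consistent tp={tp} gives {tp / n_pos:.{decimals}f}")
    if abs(specificity(cm) - spc) > tol:
        bad.append(f"specificity: nearest consistent tn={tn} gives {tn / n_neg:.{decimals}f}")
    if bad:
        raise EvaluationError(
            "rates are not consistent with integer counts at the printed "
            "precision (" + "; ".join(bad) + ")"
        )
    return cm


# ---------------------------------------------------------------------------
# Clinical utility index


CUI_GRADES = (("excellent", 0.81), ("good", 0.64), ("satisfactory", 0.49))


def cui_grade(value: float) -> str:
    for name, cut in CUI_GRADES:
        if value >= cut:
            return name
    return "poor"


@dataclass(frozen=True)
class CUIReport:
    cui_plus: float
    cui_minus: float
    grade_plus: str
    grade_minus: str


def cui(cm: ConfusionMatrix) -> CUIReport:
    """Clinical utility indices with qualitative grades.

    Convention for degenerate predictive values: a test that makes no false
    positive calls but some true positives has PPV 1 (every positive call is
    right), and symmetrically NPV 1 when fn = 0 with tn > 0.  This is needed
    to evaluate raters who never call a control positive (specificity 100%).
    """
    sen = sensitivity(cm)
    spc = specificity(cm)
    if cm.tp + cm.fp == 0:
        raise EvaluationError("cui_plus undefined: no predicted positives")
    p = 1.0 if (cm.fp == 0 and cm.tp > 0) else ppv(cm)
    if cm.tn + cm.fn == 0:
        raise EvaluationError("cui_minus undefined: no predicted negatives")
    n = 1.0 if (cm.fn == 0 and cm.tn > 0) else npv(cm)
    plus = sen * p
    minus = spc * n
    return CUIReport(plus, minus, cui_grade(plus), cui_grade(minus))


# ---------------------------------------------------------------------------
# ROC curves


@dataclass(frozen=True)
class ROCCurve:
    """Operating points (fpr, tpr) with their generating thresholds.

    Points are sorted by (fpr, tpr).  ``thresholds`` aligns with ``points``;
    the sentinel thresholds below the minimum score and above the maximum
    produce the (1, 1) and (0, 0) corners.
    """

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        for fpr, tpr in self.points:
            if not (0 <= fpr <= 1 and 0 <= tpr <= 1):
                raise EvaluationError("ROC points must lie in the unit square")

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def roc_from_scores(labels: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """Threshold sweep: one operating point per distinct score plus sentinels.

    A record is called positive when its score is strictly greater than the
    threshold, matching the classifier's decision rule.
    """
    lab = np.asarray(labels, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if lab.min() == lab.max():
        raise EvaluationError("ROC needs both classes in the evaluation set")
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    distinct = np.unique(sc)
    span = max(distinct[-1] - distinct[0], 1.0)
    thresholds = np.concatenate(
        [[distinct[0] - 0.01 * span], distinct, [distinct[-1] + 0.01 * span]]
    )
    pts = []
    for th in thresholds:
        pred = sc > th
        tpr = int((pred & (lab == 1)).sum()) / n_pos
        fpr = int((pred & (lab == 0)).sum()) / n_neg
        pts.append((float(th), fpr, tpr))
    pts.sort(key=lambda p: (p[1], p[2]))
    return ROCCurve(
        points=tuple((fpr, tpr) for _, fpr, tpr in pts),
        thresholds=tuple(th for th, _, _ in pts),
    )


def roc_sweep(model: CPNModel, test: Cohort) -> ROCCurve:
    """ROC of a trained network on a held-out cohort, sweeping the readout threshold."""
    test.require_both_classes()
    return roc_from_scores(test.labels, model.score_cohort(test))


def convex_hull(curve: ROCCurve) -> ROCCurve:
    """Upper convex hull of the ROC points together with (0,0) and (1,1).

    The hull dominates the raw curve: every hull point is an achievable
    operating characteristic (possibly by randomizing between thresholds),
    and the hull AUC is never below the raw AUC.
    """
    pairs = {(0.0, 0.0): math.nan, (1.0, 1.0): math.nan}
    for (f, t), th in zip(curve.points, curve.thresholds):
        key = (float(f), float(t))
        if key not in pairs or math.isnan(pairs[key]):
            pairs[key] = th
    pts = sorted(pairs)
    # Andrew monotone chain, upper envelope on (fpr, tpr)
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2 and _cross(hull[-2], hull[-1], p) >= 0:
            hull.pop()
        hull.append(p)
    return ROCCurve(
        points=tuple(hull), thresholds=tuple(pairs[p] for p in hull)
    )


def _cross(o: tuple[float, float], a: tuple[float, float], b: tuple[float, float]) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def auc(curve: ROCCurve) -> float:
    """Area under the curve by the trapezoid rule on fpr-sorted points."""
    order = np.lexsort((curve.tpr, curve.fpr))
    return float(np.trapezoid(curve.tpr[order], curve.fpr[order]))


def balanced_threshold(curve: ROCCurve) -> float:
    """The sweep threshold whose sensitivity and specificity are most similar.

    Ties are broken toward higher sensitivity.  Sentinel corner points carry
    real thresholds and participate; hull-interpolated corners (NaN
    thresholds) do not.
    """
    best: tuple[float, float, float] | None = None
    for (fpr, tpr), th in zip(curve.points, curve.thresholds):
        if math.isnan(th):
            continue
        gap = abs(tpr - (1.0 - fpr))
        if best is None or gap < best[0] - 1e-12 or (
            abs(gap - best[0]) <= 1e-12 and tpr > best[1]
        ):
            best = (gap, tpr, th)
    if best is None:
        raise EvaluationError("curve carries no thresholds")
    return best[2]


def evaluate_at_threshold(
    model: CPNModel, test: Cohort, threshold: float | None = None
) -> ConfusionMatrix:
    """Confusion matrix of the network on a cohort at a given (or its own) threshold."""
    th = model.threshold if threshold is None else threshold
    scores = model.score_cohort(test)
    return confusion_matrix(test.labels, (scores > th).astype(int))


# ---------------------------------------------------------------------------
# Single-scale cut-offs


ORIENTATIONS: dict[str, str] = {
    "mmse": "lower-is-impaired",
    "faq": "higher-is-impaired",
    "gds": "higher-is-impaired",
}


@dataclass(frozen=True)
class CutoffResult:
    """Optimum integer cut-off of a single clinical scale as a classifier."""

    scale: str
    cutoff_label: str  # e.g. "0/1": boundary between the two adjacent scores
    cutoff_value: float  # midpoint actually used for the decision
    cm: ConfusionMatrix
    curve: ROCCurve


def best_scale_cutoff(
    test: Cohort,
    scale: str,
    orientation: Literal["higher-is-impaired", "lower-is-impaired"] | None = None,
) -> CutoffResult:
    """Sweep all integer mid-point cut-offs of one scale as a univariate test.

    For higher-is-impaired scales (FAQ, GDS) a subject is called MCI when the
    score is strictly above the cut-off; for lower-is-impaired scales (MMSE)
    when strictly below.  Returns the cut-off maximizing accuracy, ties
    broken toward higher sensitivity, plus the full univariate ROC.
    """
    test.require_both_classes()
    orientation = orientation or ORIENTATIONS.get(scale)
    if orientation not in ("higher-is-impaired", "lower-is-impaired"):
        raise EvaluationError(f"orientation required for scale {scale!r}")
    values = np.array([r.feature(scale) for r in test.records])
    labels = test.labels
    if values.min() == values.max():
        raise EvaluationError(f"scale {scale!r} is constant on this cohort")
    # impairment score: larger = more likely MCI under either orientation
    impairment = values if orientation == "higher-is-impaired" else -values
    curve = roc_from_scores(labels, impairment)

    lo, hi = int(values.min()), int(values.max())
    best: CutoffResult | None = None
    best_key: tuple[float, float] | None = None
    for v in range(lo, hi):
        mid = v + 0.5
        if orientation == "higher-is-impaired":
            pred = (values > mid).astype(int)
            label = f"{v}/{v + 1}"
        else:
            pred = (values < mid).astype(int)
            label = f"{v}/{v + 1}"
        cm = confusion_matrix(labels, pred)
        key = (accuracy(cm), sensitivity(cm))
        if best_key is None or key > best_key:
            best_key = key
            best = CutoffResult(scale, label, mid, cm, curve)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Pooled summaries


def pooled_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of a set of rates (pooled rater performance)."""
    if len(values) == 0:
        raise EvaluationError("pooled_mean of empty list")
    return float(np.mean(values))
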