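"""Evaluation against self-reported smoking status.

Implements the validation protocol used for methylation smoking
classifiers: a 3x3 confusion matrix (reference x predicted), one-vs-rest
sensitivity/specificity and balanced accuracy per class, overall
accuracy, a 2-class (current vs never) evaluation that excludes
self-reported former smokers, and Spearman rank correlation of the
ordinal-coded predicted status (current=1, former=2, never=3) against
continuous exposure covariates such as blood cotinine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labels import STATUS_ORDER, SmokingStatus

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "one_vs_rest_metrics",
    "overall_accuracy",
    "two_class_evaluation",
    "spearman_ordinal",
    "evaluate_predictions",
    "COTININE_RECENCY_THRESHOLD_NG_ML",
]

#: Annotation constant: blood cotinine above this level indicates smoking
#: within ~24 h of the blood draw. Not used in any computation.
COTININE_RECENCY_THRESHOLD_NG_ML = 10.0


def _as_status_list(values) -> list:
    out = []
    for v in values:
        out.append(v if isinstance(v, SmokingStatus) else SmokingStatus.from_label(str(v)))
    return out


@dataclass
class ConfusionMatrix:
    """3x3 cross-tabulation; rows = reference status, columns = predicted."""

    counts: np.ndarray
    class_order: tuple = STATUS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3 (current, former, never)")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        labels = [s.label for s in self.class_order]
        return pd.DataFrame(self.counts, index=pd.Index(labels, name="reference"),
                            columns=pd.Index(labels, name="predicted"))


def confusion_matrix(reference: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Exact cross-tabulation of reference vs predicted statuses."""
    ref = _as_status_list(reference)
    pred = _as_status_list(predicted)
    if len(ref) != len(pred):
        raise ValueError(f"length mismatch: {len(ref)} reference vs {len(pred)} predicted")
    if not ref:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    counts = np.zeros((3, 3), dtype=int)
    for r, p in zip(ref, pred):
        counts[STATUS_ORDER.index(r), STATUS_ORDER.index(p)] += 1
    return ConfusionMatrix(counts)


def one_vs_rest_metrics(cm: ConfusionMatrix, cls: SmokingStatus):
    """Sensitivity, specificity and balanced accuracy of one class vs the rest.

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP),
    balanced accuracy = their mean. When the class has no reference
    samples the sensitivity (and balanced accuracy) is undefined and
    reported as NaN with a warning.
    """
    cls = cls if isinstance(cls, SmokingStatus) else SmokingStatus.from_label(str(cls))
    i = STATUS_ORDER.index(cls)
    counts = cm.counts
    tp = counts[i, i]
    fn = counts[i, :].sum() - tp
    fp = counts[:, i].sum() - tp
    tn = counts.sum() - tp - fn - fp
    if tp + fn == 0:
        warnings.warn(f"no reference samples for class {cls.label!r}; "
                      "sensitivity undefined", UserWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    balanced = (sens + spec) / 2.0
    return float(sens), float(spec), float(balanced)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly classified samples: trace / total."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class TwoClassMetrics:
    """Current-vs-never evaluation with reference former smokers removed."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    overall_accuracy: float
    n_current: int
    n_never: int
    n_former_excluded: int


def two_class_evaluation(reference: Sequence, predicted_2class: Sequence) -> TwoClassMetrics:
    """Current-vs-never metrics, excluding self-reported former smokers.

    ``predicted_2class`` must come from two-class-mode prediction (calls in
    {current, never} only). Sensitivity is for the current-smoker class.
    """
    ref = _as_status_list(reference)
    pred = _as_status_list(predicted_2class)
    if len(ref) != len(pred):
        raise ValueError("length mismatch between reference and predictions")
    keep = [(r, p) for r, p in zip(ref, pred) if r != SmokingStatus.FORMER]
    n_former = len(ref) - len(keep)
    if any(p == SmokingStatus.FORMER for _, p in keep):
        raise ValueError("two-class evaluation requires two-class-mode predictions")
    n_cur = sum(1 for r, _ in keep if r == SmokingStatus.CURRENT)
    n_nev = sum(1 for r, _ in keep if r == SmokingStatus.NEVER)
    if n_cur == 0 or n_nev == 0:
        raise ValueError("two-class evaluation needs both current and never "
                         "reference samples")
    tp = sum(1 for r, p in keep if r == SmokingStatus.CURRENT and p == SmokingStatus.CURRENT)
    tn = sum(1 for r, p in keep if r == SmokingStatus.NEVER and p == SmokingStatus.NEVER)
    sens = tp / n_cur
    spec = tn / n_nev
    return TwoClassMetrics(
        sensitivity=float(sens),
        specificity=float(spec),
        balanced_accuracy=float((sens + spec) / 2.0),
        overall_accuracy=float((tp + tn) / (n_cur + n_nev)),
        n_current=n_cur,
        n_never=n_nev,
        n_former_excluded=n_former,
    )


@dataclass
class MetricsReport:
    """Full evaluation: confusion matrix, per-class and overall metrics."""

    cm: ConfusionMatrix
    per_class: dict  # label -> {"sensitivity", "specificity", "balanced_accuracy"}
    overall_accuracy: float
    two_class: Optional[TwoClassMetrics] = None
    annotations: dict = field(default_factory=lambda: {
        "cotinine_recency_threshold_ng_ml": COTININE_RECENCY_THRESHOLD_NG_ML
    })

    def to_dict(self) -> dict:
        out = {
            "confusion_matrix": self.cm.counts.tolist(),
            "class_order": [s.label for s in self.cm.class_order],
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "annotations": self.annotations,
        }
        if self.two_class is not None:
            out["two_class"] = vars(self.two_class).copy()
        return out


def evaluate_predictions(reference: Sequence, predicted_3class: Sequence,
                         predicted_2class: Optional[Sequence] = None) -> MetricsReport:
    """One-stop evaluation producing a :class:`MetricsReport`."""
    cm = confusion_matrix(reference, predicted_3class)
    per_class = {}
    for cls in STATUS_ORDER:
        sens, spec, bal = one_vs_rest_metrics(cm, cls)
        per_class[cls.label] = {
            "sensitivity": sens, "specificity": spec, "balanced_accuracy": bal,
        }
    two = None
    if predicted_2class is not None:
        two = two_class_evaluation(reference, predicted_2class)
    return MetricsReport(cm=cm, per_class=per_class,
                         overall_accuracy=overall_accuracy(cm), two_class=two)


def spearman_ordinal(statuses: Sequence, covariate: Sequence[float]):
    """Spearman correlation of ordinal-coded status vs a continuous covariate.

    Statuses are coded current=1, former=2, never=3 (so hypomethylation
    biomarkers and cotinine correlate *negatively* with the code).
    Midrank ties, two-sided p-value from the standard large-sample
    approximation. Pairs with a missing covariate are dropped. A constant
    covariate leaves rho undefined (NaN, with a warning).
    """
    codes = np.array([int(s) for s in _as_status_list(statuses)], dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if len(codes) != len(cov):
        raise ValueError("length mismatch between statuses and covariate")
    keep = ~np.isnan(cov)
    codes, cov = codes[keep], cov[keep]
    if len(codes) < 3:
        raise ValueError("need at least 3 complete pairs for a rank correlation")
    if np.all(cov == cov[0]) or np.all(codes == codes[0]):
        warnings.warn("constant input: Spearman rho undefined", UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(codes, cov)
    return float(rho), float(p)
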