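"""Binary-classification metric suite built on confusion counts.

The framework reports, for each classifier: accuracy, balanced accuracy,
precision, specificity, recall (sensitivity), F1, Dice, overlap index, IoU,
AUC, Youden index, and cosine similarity.  For binary confusion counts Dice
and F1 are the same quantity, and the Youden index equals
``2 * balanced accuracy - 100%``; both identities are exercised by tests.

The "overlap index" here is an alias of Dice, which is how the framework
tabulates it; the conventional overlap (Szymkiewicz-Simpson) coefficient
``TP / min(TP+FP, TP+FN)`` is available as ``overlap_coefficient``.

Ratios with a zero denominator report 0 and set a degenerate flag on the
report instead of raising, so an optimizer driving on these metrics never
sees an exception from a pathological candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_predictions",
    "compute_metrics",
    "overlap_coefficient",
    "auc_from_scores",
    "cosine_similarity_metric",
    "format_percent",
]

#: Row order of the tabulated report.
REPORT_ROWS = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "specificity",
    "recall",
    "f1",
    "dice",
    "overlap_index",
    "iou",
    "auc",
    "youden",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts for one binary evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Metric values as fractions in [0, 1] (youden in [-1, 1]).

    ``degenerate`` lists metrics whose denominator was zero (reported as 0).
    ``as_percentages`` / ``format_rows`` give the percent-scale view used in
    tabulated output, rounded half-up to two decimals.
    """

    values: dict[str, float]
    degenerate: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_percentages(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.values.items()}

    def format_rows(self) -> dict[str, str]:
        return {k: format_percent(v) for k, v in self.values.items()}


def format_percent(fraction: float) -> str:
    """Render a fraction as a percent string, half-up to 2 decimals (96.09 %)."""
    q = Decimal(repr(fraction * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if q == q.to_integral_value():
        return f"{int(q)} %"
    return f"{q} %"


def confusion_from_predictions(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Count TP/TN/FP/FN with the declared positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"expected binary labels, got {sorted(map(str, labels))}")
    t = y_true == positive_label
    p = y_pred == positive_label
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Compute the full suite from confusion counts.

    When no score-based AUC is supplied, AUC defaults to the hard-prediction
    value (recall + specificity)/2, i.e. balanced accuracy.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated samples")
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    deg: list[str] = []
    accuracy = (TP + TN) / counts.total
    precision = _ratio(TP, TP + FP, "precision", deg)
    specificity = _ratio(TN, TN + FP, "specificity", deg)
    recall = _ratio(TP, TP + FN, "recall", deg)
    dice = _ratio(2 * TP, 2 * TP + FP + FN, "dice", deg)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", deg)
    iou = _ratio(TP, TP + FP + FN, "iou", deg)
    balanced = (recall + specificity) / 2
    youden = specificity + recall - 1.0
    values = {
        "accuracy": accuracy,
        "balanced_accuracy": balanced,
        "precision": precision,
        "specificity": specificity,
        "recall": recall,
        "f1": f1,
        "dice": dice,
        "overlap_index": dice,
        "iou": iou,
        "auc": balanced if auc is None else float(auc),
        "youden": youden,
    }
    return MetricReport(values=values, degenerate=deg)


def overlap_coefficient(counts: ConfusionCounts) -> float:
    """Conventional overlap coefficient TP / min(TP+FP, TP+FN) (0 if undefined)."""
    den = min(counts.TP + counts.FP, counts.TP + counts.FN)
    return counts.TP / den if den else 0.0


def auc_from_scores(y_true, scores, positive_label=None) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2.

    For hard 0/1 predictions this equals balanced accuracy.  Raises on a
    single-class truth vector, where the AUC is undefined.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    if positive_label is None:
        positive_label = classes[-1]
    return float(roc_auc_score((y_true == positive_label).astype(int), scores))


def cosine_similarity_metric(y_true_onehot, y_prob) -> tuple[float, int]:
    """Mean per-sample cosine between probability rows and one-hot truth rows.

    Returns ``(mean cosine, n_skipped)`` where zero-norm rows are skipped.
    """
    T = np.asarray(y_true_onehot, dtype=float)
    P = np.asarray(y_prob, dtype=float)
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {P.shape}")
    tn = np.linalg.norm(T, axis=1)
    pn = np.linalg.norm(P, axis=1)
    ok = (tn > 0) & (pn > 0)
    n_skipped = int(np.sum(~ok))
    if not ok.any():
        raise ValueError("all rows have zero norm")
    cos = np.sum(T[ok] * P[ok], axis=1) / (tn[ok] * pn[ok])
    return float(cos.mean()), n_skipped
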