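"""Binary-classification metrics: SN, SP, ACC, PR, F1, MCC, AUC.

Threshold metrics are computed from the 2x2 confusion counts; metrics with a
zero denominator are reported as explicitly undefined (``None`` plus a flag),
never silently zero.  AUC uses the rank (Mann-Whitney) formulation: the
probability that a random positive outscores a random negative, with ties
credited one half — identical to the area under the full-threshold ROC
polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.stats import rankdata

from .errors import CppkitError, LengthMismatchError, SingleClassError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "metrics_from_counts", "auc", "evaluate_predictions"]

METRIC_NAMES = ("sn", "sp", "acc", "pr", "f1", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise CppkitError("confusion counts must be non-negative")
        if self.total == 0:
            raise CppkitError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Metric values; an entry is ``None`` iff its name is in ``undefined``."""

    sn: float | None = None
    sp: float | None = None
    acc: float | None = None
    pr: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auc: float | None = None
    undefined: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "undefined"}

    def formatted(self) -> dict[str, str]:
        """Values for display; undefined entries print as an en-dash."""
        return {
            k: ("–" if v is None else f"{v:.4f}") for k, v in self.as_dict().items()
        }


def confusion_counts(truth, predicted) -> ConfusionCounts:
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise LengthMismatchError("truth and predictions differ in length")
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (predicted == 1))),
        fp=int(np.sum((truth == 0) & (predicted == 1))),
        tn=int(np.sum((truth == 0) & (predicted == 0))),
        fn=int(np.sum((truth == 1) & (predicted == 0))),
    )


def _ratio(num: float, den: float, name: str, report: MetricsReport) -> float | None:
    if den == 0:
        report.undefined.add(name)
        return None
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts (AUC needs scores; see :func:`auc`).

    SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total, PR = TP/(TP+FP),
    F1 = 2·PR·SN/(PR+SN),
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    report = MetricsReport()
    report.sn = _ratio(c.tp, c.tp + c.fn, "sn", report)
    report.sp = _ratio(c.tn, c.tn + c.fp, "sp", report)
    report.acc = (c.tp + c.tn) / c.total
    report.pr = _ratio(c.tp, c.tp + c.fp, "pr", report)
    if report.pr is None or report.sn is None or (report.pr + report.sn) == 0:
        report.undefined.add("f1")
    else:
        report.f1 = 2 * report.pr * report.sn / (report.pr + report.sn)
    denom = (
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        report.undefined.add("mcc")
    else:
        report.mcc = (float(c.tp) * c.tn - float(c.fp) * c.fn) / np.sqrt(denom)
    report.undefined.add("auc")  # counts alone cannot yield AUC
    return report


def auc(scores, labels) -> float:
    """Rank-based AUC: U / (n1·n0) with tie credit one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise LengthMismatchError("scores and labels differ in length")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUC needs both classes")
    ranks = rankdata(scores)
    u1 = float(np.sum(ranks[labels == 1])) - n1 * (n1 + 1) / 2.0
    return u1 / (n1 * n0)


def evaluate_predictions(truth, predicted, scores=None) -> MetricsReport:
    """Full report from hard labels plus (optionally) continuous scores."""
    report = metrics_from_counts(confusion_counts(truth, predicted))
    if scores is not None:
        report.undefined.discard("auc")
        report.auc = auc(scores, truth)
    return report
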