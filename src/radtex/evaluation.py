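"""Performance battery: confusion matrix, AC/MCC/SN/SP/PPV and ROC/AUC.

Percentage metrics are computed at full precision (``x 100``) and the
report additionally carries nearest-integer roundings (MCC rounded to two
decimals), since published tables usually print integers.  Degenerate
denominators yield flagged NaN (or 0 for MCC) rather than exceptions, so
batch evaluation never aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import (
    FeatureTable,
    LESION_LABEL,
    SplitSpec,
    TrainedModel,
    fit,
    predict,
    relabel_lesion_vs_normal,
    split_dataset,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts: positive = abnormal (lesion present)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        counts = (self.TP, self.TN, self.FP, self.FN)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one outcome")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str = LESION_LABEL,
) -> ConfusionMatrix:
    """Tally binary outcomes against *positive_class*."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label sequences differ in length: "
            f"{len(true_labels)} vs {len(predicted_labels)}"
        )
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        t_pos = t == positive_class
        p_pos = p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and not p_pos:
            tn += 1
        elif p_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """``(TP + TN) / total`` as a full-precision percentage."""
    return 100.0 * (cm.TP + cm.TN) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in ``[-1, 1]``.

    When any marginal factor of the denominator is zero the value is
    defined as 0 and a degeneracy warning is emitted.
    """
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom == 0:
        warnings.warn("degenerate confusion matrix: MCC defined as 0")
        return 0.0
    return (cm.TP * cm.TN - cm.FP * cm.FN) / np.sqrt(float(denom))


def _ratio_percent(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: denominator is 0")
        return float("nan")
    return 100.0 * num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """``TP / (TP + FN)`` as a percentage; NaN (flagged) if undefined."""
    return _ratio_percent(cm.TP, cm.TP + cm.FN, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """``TN / (TN + FP)`` as a percentage; NaN (flagged) if undefined."""
    return _ratio_percent(cm.TN, cm.TN + cm.FP, "specificity")


def ppv(cm: ConfusionMatrix) -> float:
    """``TP / (TP + FP)`` as a percentage; NaN (flagged) if undefined."""
    return _ratio_percent(cm.TP, cm.TP + cm.FP, "ppv")


@dataclass(frozen=True)
class MetricsReport:
    """Full-precision metrics plus print-style roundings and flags."""

    cm: ConfusionMatrix
    ac: float
    mcc: float
    sn: float
    sp: float
    ppv: float
    degenerate: tuple[str, ...] = ()

    @property
    def rounded(self) -> dict[str, float]:
        """Nearest-integer percents; MCC to two decimals."""
        out = {}
        for name, value in (("ac", self.ac), ("sn", self.sn), ("sp", self.sp), ("ppv", self.ppv)):
            out[name] = float("nan") if np.isnan(value) else int(round(value))
        out["mcc"] = round(self.mcc, 2)
        return out

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.cm.TP, "TN": self.cm.TN, "FP": self.cm.FP, "FN": self.cm.FN},
            "ac_percent": self.ac,
            "mcc": self.mcc,
            "sn_percent": self.sn,
            "sp_percent": self.sp,
            "ppv_percent": self.ppv,
            "rounded": self.rounded,
            "degenerate": list(self.degenerate),
        }


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Compute every scalar metric of one confusion matrix."""
    degenerate = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = {
            "ac": accuracy(cm),
            "mcc": mcc(cm),
            "sn": sensitivity(cm),
            "sp": specificity(cm),
            "ppv": ppv(cm),
        }
    if (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN) == 0:
        degenerate.append("mcc")
    for name, value in values.items():
        if name != "mcc" and np.isnan(value):
            degenerate.append(name)
    return MetricsReport(cm=cm, degenerate=tuple(degenerate), **values)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep operating points from (0,0) to (1,1), plus AUC."""

    fpf: np.ndarray
    tpf: np.ndarray
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpf, self.fpf))


def roc_curve(
    scores: Sequence[float],
    true_labels: Sequence[str],
    positive_class: str = LESION_LABEL,
) -> ROCCurve:
    """Sweep a threshold over the distinct scores (ties grouped).

    The trapezoidal area under the resulting curve equals the
    Mann–Whitney probability of correct ranking with half credit for
    ties.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(true_labels):
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    truth = np.array([lab == positive_class for lab in true_labels])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    # keep only the last index of each tie group
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tp_cum = np.cumsum(sorted_truth)[distinct]
    fp_cum = np.cumsum(~sorted_truth)[distinct]
    tpf = np.r_[0.0, tp_cum / n_pos]
    fpf = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return ROCCurve(fpf=fpf, tpf=tpf, thresholds=thresholds)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return curve.auc


@dataclass(frozen=True)
class MethodEvaluation:
    """Hold-out evaluation artifacts of one feature method."""

    method: str
    model: TrainedModel
    report: MetricsReport
    roc: ROCCurve | None

    def to_dict(self) -> dict:
        out = {"method": self.method, **self.report.to_dict()}
        out["auc"] = None if self.roc is None else self.roc.auc
        return out


def evaluate_method(
    table: FeatureTable,
    split_spec: SplitSpec = SplitSpec(),
    task: str = "lesion-vs-normal",
) -> MethodEvaluation:
    """Split, train and score one feature table end to end.

    ``task="lesion-vs-normal"`` collapses the lesion classes into one
    positive class (the published evaluation layout); any other task is
    interpreted as ``"<positive>-vs-<negative>"`` over the raw labels.
    """
    if task == "lesion-vs-normal":
        table = relabel_lesion_vs_normal(table)
        positive = LESION_LABEL
    else:
        try:
            positive, negative = task.split("-vs-")
        except ValueError:
            raise ValueError(f"unrecognized task {task!r}") from None
        keep = [i for i, lab in enumerate(table.labels) if lab in (positive, negative)]
        table = table.subset(keep)
    train, test = split_dataset(table, split_spec)
    if len(test) == 0:
        raise ValueError("test split is empty")
    model = fit(train)
    pred, scores = predict(model, test)
    cm = confusion(test.labels, pred, positive_class=positive)
    report = metrics_report(cm)
    roc = None
    if len(model.classes) == 2 and len(set(test.labels)) == 2:
        signed = scores if model.positive_class == positive else -scores
        roc = roc_curve(signed, test.labels, positive_class=positive)
    return MethodEvaluation(method=table.method, model=model, report=report, roc=roc)
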