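"""Metric battery over known + unknown labels.

Everything is computed from first principles off the confusion matrix (or,
for the curves, off per-sample probability vectors) so the conventions are
explicit and testable:

* precision/recall/F1 use the zero-denominator → 0 convention;
* macro averages run over labels with support or predictions (both
  configurable facts are documented on each function);
* balanced accuracy is the mean recall over labels with support;
* MCC uses the generalized multiclass covariance form;
* ROC curves are one-vs-rest with trapezoidal AUC, precision-recall curves
  are step-wise (no interpolation) with AUPRC the step sum;
* the micro-average pools every (sample, label) decision.

The threshold sweep re-runs the model's rejection rule at each cutoff ε and
reports the full column set per row, thresholds in descending order. The
"f1" column is micro-F1, which coincides with accuracy for single-label
multiclass decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .openset import OpenSetModel, predict_openmax, predict_score_threshold
from .types import UNKNOWN_LABEL, ActivationRecord, ActivationSet


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows are truth, columns are prediction, in ``labels`` order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise InvalidArgumentError(
                f"counts shape {counts.shape} does not match {len(self.labels)} labels"
            )
        if (counts < 0).any():
            raise InvalidArgumentError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized view (rows with zero support stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Tally truth/prediction pairs; labels outside ``labels`` are an error."""
    if len(truth) != len(predicted):
        raise InvalidArgumentError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) differ in length"
        )
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise InvalidArgumentError(f"unseen truth label {t!r}")
        if p not in index:
            raise InvalidArgumentError(f"unseen predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate and per-class classification metrics."""

    accuracy: float
    balanced_accuracy: float
    mcc: float
    per_class: pd.DataFrame  # label, precision, recall, f1, support
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    auprc_macro: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "macro_avg": dict(self.macro_avg),
            "weighted_avg": dict(self.weighted_avg),
            "auprc_macro": self.auprc_macro,
            "per_class": self.per_class.to_dict(orient="records"),
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision/recall/F1 (zero-denominator → 0), macro and weighted
    averages, balanced accuracy, and multiclass MCC, all from the matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise InvalidArgumentError("confusion matrix is empty")
    tp = np.diag(counts)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    precision = _safe_div(tp, predicted)
    recall = _safe_div(tp, support)
    f1 = _safe_div(2 * precision * recall, precision + recall)

    eligible = (support > 0) | (predicted > 0)
    macro = {
        "precision": float(precision[eligible].mean()),
        "recall": float(recall[eligible].mean()),
        "f1": float(f1[eligible].mean()),
    }
    weighted = {
        "precision": float((support * precision).sum() / total),
        "recall": float((support * recall).sum() / total),
        "f1": float((support * f1).sum() / total),
    }
    accuracy = float(tp.sum() / total)
    balanced = float(recall[support > 0].mean())

    # Generalized multiclass MCC, covariance form over the confusion matrix.
    cov_num = tp.sum() * total - float(predicted @ support)
    den_p = total * total - float(predicted @ predicted)
    den_t = total * total - float(support @ support)
    mcc = 0.0 if den_p <= 0 or den_t <= 0 else float(cov_num / np.sqrt(den_p * den_t))

    per_class = pd.DataFrame(
        {
            "label": list(cm.labels),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        }
    )
    return MetricsReport(
        accuracy=accuracy,
        balanced_accuracy=balanced,
        mcc=mcc,
        per_class=per_class,
        macro_avg=macro,
        weighted_avg=weighted,
    )


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


def _binary_roc(y: np.ndarray, score: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points at every unique score threshold plus trapezoidal AUC."""
    order = np.argsort(-score, kind="stable")
    y = y[order].astype(float)
    s = score[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], y.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    pos, neg = y.sum(), y.size - y.sum()
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr}), auc


def _binary_pr(y: np.ndarray, score: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Step-wise precision-recall points and AUPRC (no interpolation)."""
    order = np.argsort(-score, kind="stable")
    y = y[order].astype(float)
    s = score[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], y.size - 1]
    tps = np.cumsum(y)[distinct]
    n_pred = distinct + 1.0
    pos = y.sum()
    precision = tps / n_pred
    recall = tps / pos
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    frame = pd.DataFrame(
        {"threshold": s[distinct], "recall": recall, "precision": precision}
    )
    return frame, auprc


@dataclass(frozen=True)
class CurveSet:
    """Per-label and micro-averaged ROC/PR curves with their areas."""

    per_label: dict
    micro_roc: pd.DataFrame
    micro_auc: float
    macro_auprc: float


def roc_pr_curves(
    truth: Sequence[str],
    probabilities: np.ndarray,
    labels: Sequence[str],
) -> CurveSet:
    """One-vs-rest ROC and PR curves for every label column.

    ``probabilities`` is (n, L) aligned with ``labels`` (for OpenMax output,
    column 0 is the unknown class). A label whose truth column is single-
    class gets ``auc``/``auprc`` of None and is excluded from the macro
    average; the micro average pools all (sample, label) decisions.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth)
    if probabilities.shape != (truth.size, len(labels)):
        raise InvalidArgumentError(
            f"probabilities shape {probabilities.shape} does not match "
            f"{truth.size} samples x {len(labels)} labels"
        )
    per_label: dict[str, dict] = {}
    auprcs = []
    indicators = np.zeros_like(probabilities)
    for j, label in enumerate(labels):
        y = (truth == label).astype(float)
        indicators[:, j] = y
        if y.sum() == 0 or y.sum() == y.size:
            per_label[label] = {"roc": None, "auc": None, "pr": None, "auprc": None,
                                "undefined": True}
            continue
        roc, auc = _binary_roc(y, probabilities[:, j])
        pr, auprc = _binary_pr(y, probabilities[:, j])
        per_label[label] = {"roc": roc, "auc": auc, "pr": pr, "auprc": auprc,
                            "undefined": False}
        auprcs.append(auprc)
    micro_roc, micro_auc = _binary_roc(indicators.ravel(), probabilities.ravel())
    macro_auprc = float(np.mean(auprcs)) if auprcs else float("nan")
    return CurveSet(per_label, micro_roc, micro_auc, macro_auprc)


def curves_frame(curves: CurveSet) -> pd.DataFrame:
    """Long-format export: label, curve, threshold, x, y."""
    rows = []
    for label, entry in curves.per_label.items():
        if entry["undefined"]:
            continue
        for _, r in entry["roc"].iterrows():
            rows.append((label, "roc", r["threshold"], r["fpr"], r["tpr"]))
        for _, r in entry["pr"].iterrows():
            rows.append((label, "pr", r["threshold"], r["recall"], r["precision"]))
    for _, r in curves.micro_roc.iterrows():
        rows.append(("__micro__", "roc", r["threshold"], r["fpr"], r["tpr"]))
    return pd.DataFrame(rows, columns=["label", "curve", "threshold", "x", "y"])


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

DEFAULT_SWEEP_THRESHOLDS = (0.5, 0.4, 0.3, 0.2, 0.1)


def threshold_sweep(
    truth: Sequence[str],
    records: Iterable[ActivationRecord] | ActivationSet,
    model: OpenSetModel,
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
    decision_mode: str | None = None,
) -> pd.DataFrame:
    """Re-run the rejection rule at each ε and tabulate the metric battery.

    Rows come out in descending ε. The evaluation runs over the extended
    label set (vocabulary + unknown), so macro averages include the unknown
    class whenever it has support or predictions.
    """
    truth = list(truth)
    records = list(records)
    if len(truth) != len(records):
        raise InvalidArgumentError("truth and records differ in length")
    for eps in thresholds:
        if not 0.0 <= eps <= 1.0:
            raise InvalidArgumentError(f"threshold {eps} outside [0, 1]")
    mode = decision_mode or model.config.decision_mode
    unk = model.config.unknown_label
    labels = list(model.vocabulary) + [unk]

    from .openset import openmax_probabilities, recalibrated_scores

    score_rows = [recalibrated_scores(r.vector, model) for r in records]
    prob_rows = [openmax_probabilities(r.vector, model) for r in records]

    rows = []
    for eps in sorted(thresholds, reverse=True):
        if mode == "score_threshold":
            predicted = [
                predict_score_threshold(s, eps, model.vocabulary, unk) for s in score_rows
            ]
        else:
            predicted = [
                predict_openmax(p, eps, model.vocabulary, unk) for p in prob_rows
            ]
        cm = confusion_matrix(truth, predicted, labels)
        rep = classification_metrics(cm)
        tp = float(np.diag(cm.counts).sum())
        fp = fn = float(cm.total - tp)
        micro_f1 = 2 * tp / (2 * tp + fp + fn) if cm.total else 0.0
        rows.append(
            {
                "threshold": eps,
                "accuracy": rep.accuracy,
                "f1": micro_f1,
                "macro_precision": rep.macro_avg["precision"],
                "macro_recall": rep.macro_avg["recall"],
                "macro_f1": rep.macro_avg["f1"],
                "weighted_precision": rep.weighted_avg["precision"],
                "weighted_recall": rep.weighted_avg["recall"],
                "weighted_f1": rep.weighted_avg["f1"],
                "n_unknown_predicted": sum(p == unk for p in predicted),
            }
        )
    return pd.DataFrame(rows)
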