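"""Confusion-matrix metrics, ROC/AUC and the missing-modality protocol.

The positive class is "abnormal" (label 1).  Confusion-derived metrics
follow the standard definitions: accuracy = (TP+TN)/total, sensitivity
= TP/(TP+FN), specificity = TN/(TN+FP), FPR = FP/(FP+TN), precision =
TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN).  Ratios with a zero denominator
are reported as NaN and listed in ``MetricsReport.undefined`` rather
than silently coerced to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigurationError

THRESHOLD = 0.5  # decision threshold on the positive-class probability


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    precision: float
    f1: float
    auc: float = float("nan")
    undefined: tuple[str, ...] = ()

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """2x2 confusion counts (TP, FP, TN, FN) with positive class = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined: list[str] = []
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        fpr=_ratio(fp, fp + tn, "fpr", undefined),
        precision=_ratio(tp, tp + fp, "precision", undefined),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "f1", undefined),
        undefined=tuple(undefined),
    )


def roc_auc(y_true, scores) -> tuple[float, np.ndarray]:
    """AUC (trapezoidal, tie-averaging = Mann-Whitney) plus curve points.

    Returns ``(auc, points)`` with points as an (m, 2) array of
    (FPR, TPR) pairs from the threshold sweep.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(roc_auc_score(y_true, scores)), np.column_stack([fpr, tpr])


def metrics_report(y_true, prob_positive,
                   threshold: float = THRESHOLD) -> MetricsReport:
    """Full report (confusion metrics + AUC) from positive-class scores."""
    prob_positive = np.asarray(prob_positive, dtype=np.float64)
    y_pred = (prob_positive >= threshold).astype(int)
    report = metrics_from_confusion(*confusion(y_true, y_pred))
    if len(np.unique(np.asarray(y_true))) == 2:
        report.auc = roc_auc(y_true, prob_positive)[0]
    else:
        report.undefined = report.undefined + ("auc",)
    return report


def summarize_reports(reports: list[MetricsReport]) -> dict:
    """Fold-mean +/- sd of each metric plus pooled-confusion metrics."""
    keys = ("accuracy", "sensitivity", "specificity", "fpr", "precision",
            "f1", "auc")
    summary: dict = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=np.float64)
        summary[f"{k}_mean"] = float(np.nanmean(vals))
        summary[f"{k}_sd"] = float(np.nanstd(vals))
    pooled = metrics_from_confusion(
        sum(r.tp for r in reports), sum(r.fp for r in reports),
        sum(r.tn for r in reports), sum(r.fn for r in reports),
    )
    summary["pooled"] = pooled.as_dict()
    return summary


def write_roc_points(y_true, scores, path) -> None:
    """Write the ROC threshold sweep as a two-column (FPR, TPR) CSV."""
    _, points = roc_auc(y_true, scores)
    np.savetxt(path, points, delimiter=",", header="fpr,tpr", comments="")


def plot_confusion_matrix(report: MetricsReport, path, title: str = "") -> None:
    """Render the 2x2 confusion matrix as a heatmap figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.array([[report.tn, report.fp], [report.fn, report.tp]])
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center",
                color="black" if v < counts.max() * 0.6 else "white")
    ax.set_xticks([0, 1], ["normal", "abnormal"])
    ax.set_yticks([0, 1], ["normal", "abnormal"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


MODALITY_CHANNEL = {"ecg": 0, "pcg": 1}


def evaluate_missing_modality(model, X: np.ndarray, y: np.ndarray,
                              drop: str = "none",
                              batch_size: int = 128) -> MetricsReport:
    """Evaluate with one modality's input zeroed (``drop`` in
    {none, ecg, pcg}); the present modality is left unchanged."""
    variant = getattr(model, "variant", "full")
    if drop not in ("none", "ecg", "pcg"):
        raise ValueError(f"drop must be none/ecg/pcg, got {drop!r}")
    if drop != "none" and variant in ("single_ecg", "single_pcg"):
        raise ConfigurationError(
            f"cannot drop a modality on single-modality variant {variant}"
        )
    net = getattr(model, "network_", model)  # estimator or bare network
    if drop != "none":
        X = X.copy()
        X[:, MODALITY_CHANNEL[drop], :] = 0.0
    prob = net.predict_proba_array(X, batch_size=batch_size)[:, 1]
    return metrics_report(y, prob)
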