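"""Metrics, curves and slide-level aggregation.

Per-class metrics are one-vs-rest: each class in turn is treated as
positive against the other two, giving precision, recall, F1,
specificity, and a per-class accuracy (TP+TN)/n — the reading under
which the three classes get distinct accuracy values. ROC AUC uses the
trapezoidal rule over the full threshold sweep; PR AUC is average
precision (step-wise precision·Δrecall, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score, roc_curve)

from .config import LABELS

__all__ = ["EvalReport", "per_class_metrics", "macro_f1", "roc_pr_curves",
           "confusion", "wsi_aggregate", "evaluate_predictions"]


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    confusion: np.ndarray
    roc: dict[str, Optional[dict]] = field(default_factory=dict)
    pr: dict[str, Optional[dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "confusion": self.confusion.tolist(),
            "roc_auc": {c: (v["auc"] if v else None)
                        for c, v in self.roc.items()},
            "pr_auc": {c: (v["auc"] if v else None)
                       for c, v in self.pr.items()},
        }


def _check_labels(y: Sequence[str]) -> np.ndarray:
    y = np.asarray(y)
    bad = set(y) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return y


def per_class_metrics(y_true: Sequence[str], y_pred: Sequence[str]
                      ) -> tuple[dict[str, dict[str, float]], float]:
    """One-vs-rest contingency metrics per class plus overall accuracy.

    Undefined ratios (0/0) are reported as 0.0 with an ``undefined`` flag.
    """
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    n = len(y_true)
    per_class: dict[str, dict[str, float]] = {}
    for cls in LABELS:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        tn = n - tp - fp - fn
        undefined = []

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                undefined.append(name)
                return 0.0
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "accuracy": (tp + tn) / n if n else 0.0,
            "specificity": ratio(tn, tn + fp, "specificity"),
            "undefined": undefined,
        }
    overall = float(np.mean(y_true == y_pred)) if n else 0.0
    return per_class, overall


def macro_f1(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Unweighted mean F1 over classes present in y_true."""
    per_class, _ = per_class_metrics(y_true, y_pred)
    present = [c for c in LABELS if c in set(np.asarray(y_true))]
    if not present:
        return 0.0
    return float(np.mean([per_class[c]["f1"] for c in present]))


def roc_pr_curves(y_true: Sequence[str], probs3: np.ndarray
                  ) -> tuple[dict[str, Optional[dict]],
                             dict[str, Optional[dict]]]:
    """One-vs-rest ROC and PR curves with AUCs; absent classes → None."""
    y_true = _check_labels(y_true)
    probs3 = np.asarray(probs3, dtype=float)
    if probs3.shape != (len(y_true), len(LABELS)):
        raise ValueError("probs3 must be (n, 3)")
    if not np.allclose(probs3.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    roc: dict[str, Optional[dict]] = {}
    pr: dict[str, Optional[dict]] = {}
    for k, cls in enumerate(LABELS):
        pos = (y_true == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            roc[cls] = None
            pr[cls] = None
            continue
        fpr, tpr, _ = roc_curve(pos, probs3[:, k])
        prec, rec, _ = precision_recall_curve(pos, probs3[:, k])
        roc[cls] = {"fpr": fpr, "tpr": tpr,
                    "auc": float(roc_auc_score(pos, probs3[:, k]))}
        pr[cls] = {"precision": prec, "recall": rec,
                   "auc": float(average_precision_score(pos, probs3[:, k]))}
    return roc, pr


def confusion(y_true: Sequence[str], y_pred: Sequence[str],
              normalize: str = "row") -> np.ndarray:
    """3×3 confusion matrix in fixed (Good, Medium, Bad) order.

    Row normalization divides by true-class counts; empty rows stay zero.
    """
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    mat = np.zeros((3, 3))
    index = {c: i for i, c in enumerate(LABELS)}
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    if normalize == "row":
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sums > 0, mat / sums, 0.0)
    elif normalize not in (None, "none"):
        raise ValueError("normalize must be 'row' or none")
    return mat


def wsi_aggregate(subunit_probs: pd.DataFrame | dict[str, np.ndarray]
                  ) -> dict[str, np.ndarray]:
    """Slide-level probabilities as the mean of sub-unit probability vectors.

    Accepts either a mapping slide_id → (m, 3) array or a DataFrame with a
    ``slide_id`` column and one probability column per class. Argmax ties
    resolve by the fixed (Good, Medium, Bad) order.
    """
    if isinstance(subunit_probs, pd.DataFrame):
        grouped = {sid: grp[list(LABELS)].to_numpy()
                   for sid, grp in subunit_probs.groupby("slide_id")}
    else:
        grouped = {sid: np.atleast_2d(np.asarray(arr, float))
                   for sid, arr in subunit_probs.items()}
    out = {}
    for sid, arr in grouped.items():
        if arr.shape[0] == 0:
            raise ValueError(f"slide {sid} has no sub-units")
        out[sid] = arr.mean(axis=0)
    return out


def save_curves(report: EvalReport, out_dir) -> None:
    """Write per-class ROC/PR curve CSVs and a two-panel PNG plot."""
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(11, 5))
    for cls in LABELS:
        if report.roc.get(cls):
            roc = report.roc[cls]
            pd.DataFrame({"fpr": roc["fpr"], "tpr": roc["tpr"]}).to_csv(
                out_dir / f"roc_{cls.lower()}.csv", index=False)
            ax_roc.plot(roc["fpr"], roc["tpr"],
                        label=f"{cls} (AUC {roc['auc']:.2f})")
        if report.pr.get(cls):
            pr = report.pr[cls]
            pd.DataFrame({"recall": pr["recall"],
                          "precision": pr["precision"]}).to_csv(
                out_dir / f"pr_{cls.lower()}.csv", index=False)
            ax_pr.plot(pr["recall"], pr["precision"],
                       label=f"{cls} (AP {pr['auc']:.2f})")
    ax_roc.plot([0, 1], [0, 1], "k--", linewidth=1, label="chance (0.50)")
    ax_roc.set_xlabel("false-positive rate")
    ax_roc.set_ylabel("true-positive rate")
    ax_roc.set_title("one-vs-rest ROC")
    ax_roc.legend()
    ax_pr.axhline(1 / 3, color="k", linestyle="--", linewidth=1,
                  label="chance (0.33)")
    ax_pr.set_xlabel("recall")
    ax_pr.set_ylabel("precision")
    ax_pr.set_title("one-vs-rest precision-recall")
    ax_pr.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "curves.png", dpi=150)
    plt.close(fig)


def evaluate_predictions(y_true: Sequence[str], probs3: np.ndarray
                         ) -> EvalReport:
    """Full report: argmax predictions, per-class metrics, curves, confusion."""
    probs3 = np.asarray(probs3, dtype=float)
    y_pred = [LABELS[i] for i in probs3.argmax(axis=1)]
    per_class, overall = per_class_metrics(y_true, y_pred)
    roc, pr = roc_pr_curves(y_true, probs3)
    return EvalReport(per_class=per_class, overall_accuracy=overall,
                      confusion=confusion(y_true, y_pred), roc=roc, pr=pr)
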