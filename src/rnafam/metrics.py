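"""Evaluation metrics for multi-class family prediction and rejection.

Overall performance is summarized with accuracy, Cohen's kappa and the
multiclass Matthews correlation coefficient; per-class performance with
precision/recall/F1 and their macro (unweighted) and weighted (by true
class support) averages. Functional-vs-decoy rejection is scored with the
rank-based area under the ROC curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm


@dataclass
class MetricsReport:
    accuracy: float
    kappa: float
    mcc: float
    per_class: pd.DataFrame  # columns: label, precision, recall, f1, support
    macro_f1: float
    weighted_f1: float
    confusion: np.ndarray
    classes: list[str]
    n: int
    rejected_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "mcc": self.mcc,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "n": self.n,
            "rejected_fraction": self.rejected_fraction,
        }


def classification_report(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] | None = None,
    rejected_fraction: float | None = None,
) -> MetricsReport:
    """Compute the full multi-class report over a fixed class order.

    Metrics undefined through a zero denominator (e.g. F1 of a class with
    no true or predicted members) are reported as NaN with a warning rather
    than silently as zero.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.size == 0:
        raise ValueError("cannot score an empty label vector")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    confusion = _skm.confusion_matrix(y_true, y_pred, labels=classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, support = _skm.precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=np.nan
        )
        # F1 is undefined whenever precision or recall is (zero denominator)
        f1 = np.where(np.isnan(precision) | np.isnan(recall), np.nan, f1)
        kappa = _skm.cohen_kappa_score(y_true, y_pred, labels=classes)
        mcc = _skm.matthews_corrcoef(y_true, y_pred)
        macro_f1 = float(np.nanmean(f1)) if not np.all(np.isnan(f1)) else math.nan
        w = support / support.sum()
        weighted_f1 = float(np.nansum(f1 * w)) if not np.all(np.isnan(f1)) else math.nan
    if np.isnan(f1).any():
        undefined = [c for c, v in zip(classes, f1) if np.isnan(v)]
        warnings.warn(f"F1 undefined (zero denominator) for classes: {undefined}")
    per_class = pd.DataFrame(
        {
            "label": classes,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
    )
    return MetricsReport(
        accuracy=float(_skm.accuracy_score(y_true, y_pred)),
        kappa=float(kappa),
        mcc=float(mcc),
        per_class=per_class,
        macro_f1=macro_f1,
        weighted_f1=weighted_f1,
        confusion=confusion,
        classes=classes,
        n=int(y_true.size),
        rejected_fraction=rejected_fraction,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC; ties contribute 1/2 a concordant pair.

    ``labels`` are binary with 1 = functional; ``scores`` are oriented so
    larger means more functional (use -H or D from the uncertainty module).
    """
    labels = np.asarray(list(labels))
    scores = np.asarray(list(scores), dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(_skm.roc_auc_score(labels, scores))
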