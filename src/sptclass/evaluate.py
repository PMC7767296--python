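"""Performance measures and diagnostics for mode classifiers.

Covers accuracy, per-class precision/recall/F1 with macro averages, the
row-normalised confusion matrix (rows = actual class, columns = predicted
class), permutation feature importances (mean accuracy drop after
shuffling one feature column), and the predicted-label histogram along a
generating parameter (e.g. the Hurst exponent for FBM) used to study the
labelling cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

__all__ = [
    "EvaluationReport",
    "evaluate",
    "permutation_importance",
    "predicted_label_histogram",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Classification metrics over one (y_true, y_pred) pair.

    ``confusion`` is row-normalised and unrounded; display rounding (2
    decimals, which may make rows not sum exactly to 1) happens only in
    :meth:`summary`.
    """

    classes: Tuple[str, ...]
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def per_class(self) -> pd.DataFrame:
        """Precision/recall/F1/support table, one row per class."""
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            },
            index=list(self.classes),
        )

    def to_dict(self) -> Dict:
        return {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "support": self.support.tolist(),
            "confusion": self.confusion.tolist(),
        }

    def save_json(self, path) -> None:
        from .io import atomic_write_text

        atomic_write_text(path, json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "=" * 60,
            f"Accuracy: {self.accuracy:.3f}   (n = {int(self.support.sum())})",
            "",
            f"{'class':<16}{'precision':>10}{'recall':>10}{'F1':>10}{'support':>10}",
        ]
        for i, cls in enumerate(self.classes):
            lines.append(
                f"{cls:<16}{self.precision[i]:>10.3f}{self.recall[i]:>10.3f}"
                f"{self.f1[i]:>10.3f}{int(self.support[i]):>10d}"
            )
        lines.append(
            f"{'macro average':<16}{self.macro_precision:>10.3f}"
            f"{self.macro_recall:>10.3f}{self.macro_f1:>10.3f}"
            f"{int(self.support.sum()):>10d}"
        )
        lines.append("")
        lines.append("Confusion matrix (rows = actual, columns = predicted):")
        header = " " * 16 + "".join(f"{c[:12]:>14}" for c in self.classes)
        lines.append(header)
        for i, cls in enumerate(self.classes):
            row = "".join(f"{self.confusion[i, j]:>14.2f}" for j in range(len(self.classes)))
            lines.append(f"{cls:<16}{row}")
        return "\n".join(lines)


def evaluate(y_true: Sequence[str], y_pred: Sequence[str]) -> EvaluationReport:
    """Accuracy, per-class metrics and row-normalised confusion matrix.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean
    (0 when both vanish); macro averages are unweighted class means.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    classes = tuple(sorted(set(y_true.tolist()) | set(y_pred.tolist())))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    counts = confusion_matrix(y_true, y_pred, labels=list(classes)).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    conf = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return EvaluationReport(
        classes=classes,
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        confusion=conf,
    )


def permutation_importance(
    estimator,
    features: pd.DataFrame,
    labels: Sequence[str],
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importances as accuracy drops.

    For every feature column, the importance is the baseline accuracy
    minus the mean accuracy over ``n_repeats`` independent within-column
    shuffles (other columns untouched).  Returns a table with columns
    ``feature``, ``importance`` and ``importance_std``, in the feature
    order of the table.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    res = _sk_permutation_importance(
        estimator,
        features.to_numpy(dtype=float),
        np.asarray(labels, dtype=object),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return pd.DataFrame(
        {
            "feature": list(features.columns),
            "importance": res.importances_mean,
            "importance_std": res.importances_std,
        }
    )


def predicted_label_histogram(
    param_values: Sequence[float],
    y_pred: Sequence[str],
    bin_edges: Sequence[float],
    cutoff_bounds: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Counts of predicted modes per generating-parameter bin.

    Returns a long table with columns ``bin_left``, ``bin_right``,
    ``mode`` and ``count`` (raw counts, not densities).  The optional
    ``cutoff_bounds`` — the parameter band labelled normal at generation
    time, e.g. (0.5-c, 0.5+c) for the Hurst exponent — is attached as
    ``DataFrame.attrs['cutoff_bounds']`` for overlaying.
    """
    values = np.asarray(param_values, dtype=float)
    y_pred = np.asarray(y_pred, dtype=object)
    if values.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {values.size} parameters vs {y_pred.size} predictions"
        )
    edges = np.asarray(bin_edges, dtype=float)
    rows: List[Dict] = []
    for mode in sorted(set(y_pred.tolist())):
        counts, _ = np.histogram(values[y_pred == mode], bins=edges)
        for i in range(edges.size - 1):
            rows.append(
                {
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "mode": mode,
                    "count": int(counts[i]),
                }
            )
    df = pd.DataFrame(rows, columns=["bin_left", "bin_right", "mode", "count"])
    df.attrs["cutoff_bounds"] = cutoff_bounds
    return df
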