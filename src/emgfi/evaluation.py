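"""Diagnostic performance: confusion matrices, sensitivity/specificity, costs.

The confusion matrix is laid out rows = observed etiology, columns = foreseen
(predicted) etiology, in the canonical class order (control, neurogenic,
myogenic, idiopathic).  Under unit misclassification costs the classification
cost is the fraction of misassigned subjects, so
``overall_accuracy + classification_cost = 1`` exactly.

Specificity is one-vs-rest over all non-class subjects, controls included;
this definition is documented because no alternative is printed alongside
published sEMG classification-tree reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CLASSES, FEATURE_NAMES, ValidationError, validate_labels


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (4, 4) int, rows observed, columns predicted
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def _index(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError as exc:
            raise ValidationError(f"class {cls!r} not in {self.classes}") from exc


def confusion_matrix(
    observed: Sequence[str], predicted: Sequence[str], classes: tuple[str, ...] = CLASSES
) -> ConfusionMatrix:
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValidationError("observed and predicted label sequences differ in length")
    validate_labels(observed)
    validate_labels(predicted)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for o, p in zip(observed, predicted):
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def row_percentages(cm: ConfusionMatrix, decimals: int = 2) -> np.ndarray:
    """Each cell as a percentage of its observed-class row, rounded."""
    totals = cm.row_totals.astype(float)
    if np.any(totals == 0):
        zero = [cm.classes[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"row percentage undefined for empty observed classes: {zero}")
    return np.round(cm.counts / totals[:, None] * 100.0, decimals)


def sensitivity(cm: ConfusionMatrix, cls: str) -> float:
    """Fraction of observed ``cls`` subjects assigned to ``cls``."""
    i = cm._index(cls)
    total = cm.row_totals[i]
    if total == 0:
        raise ValidationError(f"no observed {cls!r} subjects; sensitivity undefined")
    return float(cm.counts[i, i] / total)


def specificity(cm: ConfusionMatrix, cls: str) -> float:
    """One-vs-rest: fraction of non-``cls`` subjects not assigned to ``cls``."""
    i = cm._index(cls)
    non_cls = cm.n_total - cm.row_totals[i]
    if non_cls == 0:
        raise ValidationError(f"no non-{cls!r} subjects; specificity undefined")
    false_pos = cm.counts[:, i].sum() - cm.counts[i, i]
    return float((non_cls - false_pos) / non_cls)


def classification_cost(cm: ConfusionMatrix, cost_matrix: np.ndarray | None = None) -> float:
    """Total (weighted) misclassification cost per subject.

    Unit costs by default: the fraction of misclassified subjects, the
    complement of overall accuracy.
    """
    if cm.n_total == 0:
        raise ValidationError("cost undefined for an empty confusion matrix")
    k = len(cm.classes)
    if cost_matrix is None:
        cost_matrix = 1.0 - np.eye(k)
    cost_matrix = np.asarray(cost_matrix, dtype=float)
    if cost_matrix.shape != (k, k):
        raise ValidationError(f"cost matrix must be {k}x{k}")
    return float(np.sum(cm.counts * cost_matrix) / cm.n_total)


def cost_decomposition(cm: ConfusionMatrix) -> dict[str, float]:
    """Share of the total misclassifications generated by each observed class."""
    off = cm.counts.copy().astype(float)
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    if total == 0:
        return {c: 0.0 for c in cm.classes}
    return {c: float(off[i].sum() / total) for i, c in enumerate(cm.classes)}


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.n_total == 0:
        raise ValidationError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.n_total)


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Central rounding convention: a fraction rendered as a percentage."""
    return float(np.round(fraction * 100.0, decimals))


@dataclass
class DiagnosticReport:
    """All performance figures for one classifier on one labeled cohort."""

    cm: ConfusionMatrix
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    overall_accuracy: float
    classification_cost: float
    cost_decomposition: dict[str, float]
    row_percentages: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": list(self.cm.classes),
            "counts": self.cm.counts.tolist(),
            "row_percentages": self.row_percentages.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "overall_accuracy_pct": round_percent(self.overall_accuracy, 1),
            "classification_cost_pct": round_percent(self.classification_cost, 1),
            "cost_decomposition": self.cost_decomposition,
            "n_total": self.cm.n_total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Human-readable table: a counts row and a percentage row per class."""
        classes = self.cm.classes
        width = max(len(c) for c in classes) + 2
        header = "Observed".ljust(14) + "".join(c.rjust(width) for c in classes) + "   Total"
        lines = [header, "-" * len(header)]
        pct = self.row_percentages
        for i, c in enumerate(classes):
            counts = "".join(str(int(v)).rjust(width) for v in self.cm.counts[i])
            lines.append(c.ljust(14) + counts + str(int(self.cm.row_totals[i])).rjust(8))
            pcts = "".join(f"{v:.2f}%".rjust(width) for v in pct[i])
            lines.append(" ".ljust(14) + pcts)
        lines.append(
            f"overall accuracy {round_percent(self.overall_accuracy, 1)} % | "
            f"classification cost {round_percent(self.classification_cost, 1)} % "
            f"(n = {self.cm.n_total})"
        )
        return "\n".join(lines)


def report_from_confusion(cm: ConfusionMatrix) -> DiagnosticReport:
    return DiagnosticReport(
        cm=cm,
        sensitivity={c: sensitivity(cm, c) for c in cm.classes if cm.row_totals[cm._index(c)] > 0},
        specificity={c: specificity(cm, c) for c in cm.classes},
        overall_accuracy=overall_accuracy(cm),
        classification_cost=classification_cost(cm),
        cost_decomposition=cost_decomposition(cm),
        row_percentages=row_percentages(cm),
    )


def evaluate_tree(tree, cohort: pd.DataFrame) -> DiagnosticReport:
    """Resubstitution-style evaluation of a tree on a labeled cohort table."""
    if "label" not in cohort.columns:
        raise ValidationError("cohort has no 'label' column")
    unlabeled = cohort.loc[~cohort["label"].isin(CLASSES)]
    if len(unlabeled):
        ids = (
            unlabeled["subject_id"].tolist()
            if "subject_id" in unlabeled.columns
            else unlabeled.index.tolist()
        )
        raise ValidationError(f"unlabeled rows: {ids}")
    X = cohort[list(FEATURE_NAMES)].to_numpy(dtype=float)
    observed = cohort["label"].astype(str).tolist()
    predicted = tree.predict(X).tolist()
    return report_from_confusion(confusion_matrix(observed, predicted))
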