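"""Confusion-matrix performance metrics.

Given a 3x3 (or general square) confusion matrix with rows = observed
behaviour and columns = predicted behaviour, computes per-class precision,
recall, F-score and specificity, plus the overall accuracy (trace over
grand total) and macro averages. All metrics are ratios of cell sums, so a
matrix expressed in percent of the dataset is handled identically to one
in raw counts.

Per class c: TP = cell(c,c); FN = row(c) - TP; FP = col(c) - TP;
TN = total - TP - FN - FP; then precision = TP/(TP+FP),
recall = TP/(TP+FN), F = 2PR/(P+R), specificity = TN/(TN+FP).
A metric with a zero denominator is reported as absent (None) with a
warning, and excluded from the macro averages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("grazing", "non-eating", "ruminating")


@dataclass
class ConfusionMatrix:
    """Truth-by-prediction table; rows observed, columns predicted."""

    cells: np.ndarray
    class_names: tuple = DEFAULT_CLASSES
    unit: str = "count"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        k = len(self.class_names)
        if self.cells.shape != (k, k):
            raise ValueError(
                f"cells must be {k}x{k} to match {k} class names"
            )
        if np.any(self.cells < 0):
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.unit not in ("count", "percent"):
            raise ValueError(f"unit must be 'count' or 'percent', got {self.unit!r}")
        if self.unit == "percent" and not np.isclose(
                self.cells.sum(), 100.0, atol=0.5):
            raise ValueError("percent-unit matrix must total ~100")

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, unit: str = "count") -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.columns), unit=unit)


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics, all in [0, 1]."""

    class_names: tuple
    precision: dict
    recall: dict
    f_score: dict
    specificity: dict
    overall_accuracy: float
    macro: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f_score": self.f_score[c],
                    "specificity": self.specificity[c],
                }
                for c in self.class_names
            },
            "overall_accuracy": self.overall_accuracy,
            "macro": self.macro,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _safe_ratio(num: float, den: float, metric: str, cls: str):
    if den == 0:
        warnings.warn(f"{metric} undefined for class {cls!r}; reported as absent")
        return None
    return num / den


def confusion_to_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F-score/specificity and overall accuracy."""
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix has zero total")
    cells = cm.cells
    precision, recall, f_score, specificity = {}, {}, {}, {}
    for i, c in enumerate(cm.class_names):
        tp = cells[i, i]
        fn = cells[i].sum() - tp
        fp = cells[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision[c] = _safe_ratio(tp, tp + fp, "precision", c)
        recall[c] = _safe_ratio(tp, tp + fn, "recall", c)
        if precision[c] is None or recall[c] is None or \
                (precision[c] + recall[c]) == 0:
            warnings.warn(f"f_score undefined for class {c!r}; reported as absent")
            f_score[c] = None
        else:
            f_score[c] = (2 * precision[c] * recall[c]
                          / (precision[c] + recall[c]))
        specificity[c] = _safe_ratio(tn, tn + fp, "specificity", c)

    macro = {}
    for name, d in (("precision", precision), ("recall", recall),
                    ("f_score", f_score), ("specificity", specificity)):
        defined = [v for v in d.values() if v is not None]
        macro[name] = sum(defined) / len(defined) if defined else None

    return MetricsReport(
        class_names=tuple(cm.class_names),
        precision=precision, recall=recall,
        f_score=f_score, specificity=specificity,
        overall_accuracy=float(np.trace(cells)) / total,
        macro=macro,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total — the fraction classified correctly."""
    if cm.total == 0:
        raise ValueError("confusion matrix has zero total")
    return float(np.trace(cm.cells)) / cm.total


def round_half_up(value: float, digits: int = 0) -> float:
    """Deterministic round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(value: float | None, digits: int = 0) -> str:
    """Render a [0, 1] metric as a percent string, round-half-up."""
    if value is None:
        return "-"
    pct = round_half_up(100.0 * value, digits)
    if digits == 0:
        return f"{int(pct)}%"
    return f"{pct:.{digits}f}%"


def format_report(r: MetricsReport, digits: int = 0) -> str:
    """Text table with one row per class, integer-percent style by default."""
    cols = ("Precision", "Recall", "F-score", "Specificity")
    lines = ["\t".join(("Behaviour",) + cols)]
    for c in r.class_names:
        lines.append("\t".join([
            c,
            format_percent(r.precision[c], digits),
            format_percent(r.recall[c], digits),
            format_percent(r.f_score[c], digits),
            format_percent(r.specificity[c], digits),
        ]))
    lines.append(f"Overall accuracy: {format_percent(r.overall_accuracy, digits)}")
    return "\n".join(lines)
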