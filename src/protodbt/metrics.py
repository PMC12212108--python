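"""Classification metrics and report generation.

Positive class is cancer throughout.  Undefined ratios (zero denominators)
are reported as None, never silently as 0.  auROC is the rank-based
(Mann-Whitney) area, with tied scores contributing 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "classification_metrics", "auroc", "write_report", "read_report",
           "printed_value"]


def printed_value(x: float, ndigits: int = 2) -> float:
    """Round a ratio to its printed precision, half-to-even in decimal.

    Binary floats put e.g. (0.67 + 0.74)/2 an epsilon above the exact 0.705,
    which naive formatting then rounds up; cleaning the float's decimal noise
    first (repr round-trips at 17 significant digits, so 12 is safely beyond
    any honest metric precision) restores the decimal tie, which half-even
    resolves downward to 0.70.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    clean = Decimal(repr(round(x, 12)))
    q = Decimal(1).scaleb(-ndigits)
    return float(clean.quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """The same sample with class polarity reversed."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass(frozen=True)
class MetricsReport:
    balanced_accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    auroc: float | None = None
    threshold: float = 0.5
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "auroc": self.auroc,
            "threshold": self.threshold,
            "seed": self.seed,
        }

    def summary(self) -> str:
        """Human-readable metric table (B.Acc, P, R, S, auROC order)."""
        rows = [("B. Accuracy", self.balanced_accuracy),
                ("Precision", self.precision),
                ("Recall", self.recall),
                ("Specificity", self.specificity),
                ("auROC", self.auroc)]
        lines = ["Metric        Value", "-" * 19]
        for name, v in rows:
            val = "n/a" if v is None else f"{printed_value(v):.2f}"
            lines.append(f"{name:<13} {val}")
        return "\n".join(lines)


def confusion_counts(labels, predictions) -> ConfusionCounts:
    """Binary confusion counts (1 = cancer = positive)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def classification_metrics(c: ConfusionCounts, threshold: float = 0.5,
                           seed: int | None = None) -> MetricsReport:
    """R = TP/(TP+FN), P = TP/(TP+FP), S = TN/(TN+FP),
    balanced accuracy = (R + S) / 2.  Undefined metrics come back as None."""
    recall = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    specificity = _ratio(c.tn, c.tn + c.fp)
    bacc = None
    if recall is not None and specificity is not None:
        bacc = (recall + specificity) / 2.0
    return MetricsReport(balanced_accuracy=bacc, precision=precision,
                         recall=recall, specificity=specificity,
                         threshold=threshold, seed=seed)


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def write_report(metrics: MetricsReport, destination: str | Path) -> Path:
    """JSON report plus a .txt human-readable summary alongside it."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    destination.write_text(json.dumps(metrics.to_dict(), indent=2))
    destination.with_suffix(".txt").write_text(metrics.summary() + "\n")
    return destination


def read_report(path: str | Path) -> MetricsReport:
    d = json.loads(Path(path).read_text())
    return MetricsReport(**d)
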