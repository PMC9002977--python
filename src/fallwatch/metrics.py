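"""Confusion-matrix metrics, unweighted average recall, and fall roll-ups.

The headline metric is the unweighted average recall (UAR): the arithmetic
mean of the per-class recalls, one term per class, independent of class
sizes. Fall performance is additionally rolled up by direction (forward /
backward / lateral, pooling severities) and severity (hard / soft, pooling
directions), each roll-up being the unweighted mean of its constituent
class recalls. All percentages are reported on a 0-100 scale and rounded
half-up to two decimals in rendered reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .sisfall_io import FALL_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvalReport",
    "confusion",
    "per_class_metrics",
    "uar",
    "direction_uar",
    "severity_uar",
    "falls_only_average",
    "evaluate",
    "round2",
]

DIRECTION_GROUPS: dict[str, tuple[str, str]] = {
    "forward": ("FHF", "FSF"),
    "backward": ("BHF", "BSF"),
    "lateral": ("LHF", "LSF"),
}
SEVERITY_GROUPS: dict[str, tuple[str, str, str]] = {
    "hard": ("BHF", "FHF", "LHF"),
    "soft": ("BSF", "FSF", "LSF"),
}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention of the printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k} x {k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest precision/recall/specificity/F1, in percent."""

    classes: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    specificity: dict[str, float]
    f1: dict[str, float]


def confusion(y_true, y_pred, class_order: tuple[str, ...] | list[str]) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = tuple(class_order)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: true={t!r} pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _safe_ratio(num: float, den: float, what: str, cls: str) -> float:
    if den == 0:
        logger.warning("%s undefined for class %s (zero denominator); reporting 0", what, cls)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics for every class, as percentages.

    Undefined ratios (empty class, no predicted positives) are reported as 0
    with a warning so macro averages stay defined on degenerate splits.
    """
    counts = cm.counts
    total = counts.sum()
    precision, recall, specificity, f1 = {}, {}, {}, {}
    for i, cls in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        r = 100.0 * _safe_ratio(tp, tp + fn, "recall", cls)
        p = 100.0 * _safe_ratio(tp, tp + fp, "precision", cls)
        s = 100.0 * _safe_ratio(tn, tn + fp, "specificity", cls)
        f = _safe_ratio(2 * p * r, p + r, "f1", cls)
        precision[cls], recall[cls], specificity[cls], f1[cls] = p, r, s, f
    return ClassMetrics(classes=cm.classes, precision=precision, recall=recall,
                        specificity=specificity, f1=f1)


def uar(recalls) -> float:
    """Unweighted average recall: plain mean of the per-class recalls."""
    recalls = list(recalls)
    if not recalls:
        raise ValueError("uar needs at least one per-class recall")
    return float(np.mean(recalls))


def _fall_recalls(metrics: ClassMetrics, labels: tuple[str, ...]) -> list[float]:
    missing = [c for c in labels if c not in metrics.recall]
    if missing:
        raise ValueError(f"fall classes missing from metrics: {missing}")
    return [metrics.recall[c] for c in labels]


def direction_uar(metrics: ClassMetrics) -> dict[str, float]:
    """Mean fall recall per direction, pooling hard and soft severities."""
    return {
        d: uar(_fall_recalls(metrics, group)) for d, group in DIRECTION_GROUPS.items()
    }


def severity_uar(metrics: ClassMetrics) -> dict[str, float]:
    """Mean fall recall per severity, pooling the three directions."""
    return {
        s: uar(_fall_recalls(metrics, group)) for s, group in SEVERITY_GROUPS.items()
    }


def falls_only_average(metrics: ClassMetrics) -> float:
    """Unweighted mean recall over the six fall classes."""
    return uar(_fall_recalls(metrics, FALL_LABELS))


@dataclass(frozen=True)
class EvalReport:
    """Full evaluation bundle for one test run."""

    cm: ConfusionMatrix
    metrics: ClassMetrics
    uar: float
    macro_precision: float
    macro_specificity: float
    macro_f1: float
    direction: dict[str, float]
    severity: dict[str, float]
    falls_only: float

    def to_dict(self) -> dict:
        m = self.metrics
        return {
            "classes": list(self.cm.classes),
            "confusion": self.cm.counts.tolist(),
            "per_class": {
                c: {
                    "precision": round2(m.precision[c]),
                    "recall": round2(m.recall[c]),
                    "specificity": round2(m.specificity[c]),
                    "f1": round2(m.f1[c]),
                }
                for c in self.cm.classes
            },
            "uar": round2(self.uar),
            "macro_precision": round2(self.macro_precision),
            "macro_specificity": round2(self.macro_specificity),
            "macro_f1": round2(self.macro_f1),
            "direction_uar": {k: round2(v) for k, v in self.direction.items()},
            "severity_uar": {k: round2(v) for k, v in self.severity.items()},
            "falls_only_average": round2(self.falls_only),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        """Plain-text table: class, precision, recall, specificity, F1."""
        m = self.metrics
        header = f"{'Activity':<10}{'Precision (%)':>15}{'Recall (%)':>13}{'Specificity (%)':>17}{'F1-Score (%)':>14}"
        lines = [header, "-" * len(header)]
        for c in self.cm.classes:
            lines.append(
                f"{c:<10}{round2(m.precision[c]):>15.2f}{round2(m.recall[c]):>13.2f}"
                f"{round2(m.specificity[c]):>17.2f}{round2(m.f1[c]):>14.2f}"
            )
        lines.append(
            f"{'Average':<10}{round2(self.macro_precision):>15.2f}{round2(self.uar):>13.2f}"
            f"{round2(self.macro_specificity):>17.2f}{round2(self.macro_f1):>14.2f}"
        )
        return "\n".join(lines)


def evaluate(y_true, y_pred, class_order) -> EvalReport:
    """Confusion matrix, per-class metrics, UAR, and fall roll-ups.

    Direction/severity roll-ups and the falls-only average are computed only
    when all six fall classes are present in ``class_order``.
    """
    cm = confusion(y_true, y_pred, class_order)
    m = per_class_metrics(cm)
    have_falls = all(c in cm.classes for c in FALL_LABELS)
    return EvalReport(
        cm=cm,
        metrics=m,
        uar=uar(m.recall.values()),
        macro_precision=float(np.mean(list(m.precision.values()))),
        macro_specificity=float(np.mean(list(m.specificity.values()))),
        macro_f1=float(np.mean(list(m.f1.values()))),
        direction=direction_uar(m) if have_falls else {},
        severity=severity_uar(m) if have_falls else {},
        falls_only=falls_only_average(m) if have_falls else float("nan"),
    )
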