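"""Decision-boundary classifier of perceived fatigue from averaged MSE.

The positive class is "not fatigued": a session counts as TP when its
averaged MSE lies strictly above the medium's cluster-mean boundary AND its
fatigue self-report is <= the cut (default 4.0 on the 1-8 scale). This
follows from the anti-correlation between complexity and fatigue: high MSE
predicts the absence of fatigue. A session exactly on the boundary is
classed as "below". The boundary is computed on the same sessions it
classifies; reports are labeled in-sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassifierReport",
    "decision_boundary",
    "classify_session",
    "metrics_from_counts",
    "evaluate_medium",
]

CHANCE_LEVEL_PCT = 50.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassifierReport:
    medium: str | None
    boundary: float | None
    counts: ConfusionCounts
    accuracy: float  # fraction in [0, 1]
    accuracy_pct: float
    precision: float  # NaN when undefined
    recall: float
    f1: float
    undefined_metrics: list[str] = field(default_factory=list)
    chance_level_pct: float = CHANCE_LEVEL_PCT
    in_sample: bool = True


def decision_boundary(averaged_mses: Sequence[float]) -> float:
    """Arithmetic mean of a medium's averaged-MSE cluster."""
    x = np.asarray(averaged_mses, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute a boundary from an empty cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("averaged MSEs must be finite")
    return float(x.mean())


def classify_session(
    avg_mse: float,
    boundary: float,
    fatigue: int,
    fatigue_cut: float = 4.0,
) -> str:
    """Label one session as TP, TN, FP or FN under the boundary rule."""
    if not math.isfinite(avg_mse):
        raise ValueError("avg_mse must be finite")
    if not (1 <= fatigue <= 8):
        raise ValueError(f"fatigue score {fatigue} outside [1, 8]")
    above = avg_mse > boundary  # ties count as "below"
    not_fatigued = fatigue <= fatigue_cut
    if above:
        return "TP" if not_fatigued else "FP"
    return "FN" if not_fatigued else "TN"


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 from counts, exact rational arithmetic.

    Metrics with a zero denominator are returned as NaN and listed under
    ``undefined`` — never silently reported as 0.
    """
    undefined: list[str] = []
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion counts")
    accuracy = Fraction(counts.tp + counts.tn, total)
    if counts.tp + counts.fp > 0:
        precision = Fraction(counts.tp, counts.tp + counts.fp)
    else:
        precision = None
        undefined.append("precision")
    if counts.tp + counts.fn > 0:
        recall = Fraction(counts.tp, counts.tp + counts.fn)
    else:
        recall = None
        undefined.append("recall")
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
        undefined.append("f1")
    as_float = lambda v: math.nan if v is None else float(v)
    return {
        "accuracy": float(accuracy),
        "accuracy_pct": float(accuracy * 100),
        "precision": as_float(precision),
        "recall": as_float(recall),
        "f1": as_float(f1),
        "undefined": undefined,
    }


def evaluate_medium(
    sessions: Sequence[tuple[float, int]],
    medium: str | None = None,
    fatigue_cut: float = 4.0,
    boundary: float | None = None,
) -> ClassifierReport:
    """Classify one medium's ``(avg_mse, fatigue)`` pairs and report metrics.

    The boundary defaults to the cluster mean of the supplied averaged MSEs
    (in-sample, mirroring the source procedure).
    """
    pairs = [(float(m), int(f)) for m, f in sessions]
    if len(pairs) == 0:
        raise ValueError("no sessions with a fatigue score to evaluate")
    if boundary is None:
        boundary = decision_boundary([m for m, _ in pairs])
    labels = [classify_session(m, boundary, f, fatigue_cut) for m, f in pairs]
    counts = ConfusionCounts(
        tp=labels.count("TP"),
        tn=labels.count("TN"),
        fp=labels.count("FP"),
        fn=labels.count("FN"),
    )
    metrics = metrics_from_counts(counts)
    return ClassifierReport(
        medium=medium,
        boundary=boundary,
        counts=counts,
        accuracy=metrics["accuracy"],
        accuracy_pct=metrics["accuracy_pct"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        undefined_metrics=metrics["undefined"],
    )
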