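"""Polarity binary cross-entropy loss and detection evaluation metrics.

The loss family targets the class-probability and objectness terms of a
one-stage detector trained on heavily imbalanced orchard imagery.  Plain
BCE lets the flood of easy background samples drown the few hard fruit
samples; the polarity variant multiplies each sample's BCE by a sigmoid
penalty factor ``f_p`` in (0, 2) that inflates misclassified samples and
deflates confidently correct ones, widening the margin between fruit and
background.  Everything here is per-sample scalar math plus a batch
reducer -- wiring it into a detector's training loop is the caller's job.

Also provided: IoU, a greedy score-ordered box matcher, and the
precision / recall / F-beta arithmetic used to summarise detections.
"""

from __future__ import annotations

import decimal
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LogitSample",
    "PenaltyParams",
    "DetectionCounts",
    "BBox2D",
    "bce_with_logits",
    "penalty_factor",
    "polarity_bce_with_logits",
    "batch_loss",
    "iou",
    "match_detections",
    "precision_recall",
    "f_beta",
    "round_half_up",
    "boxes_to_json",
    "boxes_from_json",
    "metrics_to_json",
]


@dataclass(frozen=True)
class LogitSample:
    """A raw detector logit ``x`` with its binary ground-truth label ``y``."""

    x: float
    y: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise ValueError(f"logit must be finite, got {self.x!r}")
        if self.y not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.y!r}")


@dataclass(frozen=True)
class PenaltyParams:
    """Slope ``gamma`` of the polarity penalty sigmoid (default 20)."""

    gamma: float = 20.0

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be a positive finite real, got {self.gamma!r}")


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("detection counts must be non-negative")


@dataclass(frozen=True)
class BBox2D:
    """Axis-aligned pixel box, 0-based, half-open [u_min,u_max) x [v_min,v_max)."""

    u_min: float
    v_min: float
    u_max: float
    v_max: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.u_min < self.u_max and self.v_min < self.v_max):
            raise ValueError(f"degenerate box {self!r}")

    @property
    def area(self) -> float:
        return (self.u_max - self.u_min) * (self.v_max - self.v_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.u_min + self.u_max) / 2.0, (self.v_min + self.v_max) / 2.0)


def bce_with_logits(sample: LogitSample) -> float:
    """Binary cross-entropy evaluated directly on the logit.

    Computed as ``log(1 + e^x) - x*y`` via log-sum-exp, which is finite and
    accurate for any representable logit (no intermediate sigmoid).
    """
    return float(np.logaddexp(0.0, sample.x) - sample.x * sample.y)


def penalty_factor(z_true: float, params: PenaltyParams = PenaltyParams()) -> float:
    """Polarity penalty ``f_p = 2 / (1 + exp(-gamma*(z_bar - z_true)))``.

    ``z_true`` is the predicted probability of the true class and
    ``z_bar = 1 - z_true`` that of the wrong class.  The factor is strictly
    decreasing in ``z_true``, equals 1 at 0.5, approaches 2 for confident
    mistakes and 0 for confident correct predictions.
    """
    if not (0.0 <= z_true <= 1.0):
        raise ValueError(f"z_true must lie in [0, 1], got {z_true!r}")
    # z_bar - z_true == 1 - 2*z_true
    t = params.gamma * (1.0 - 2.0 * z_true)
    if t >= 0:
        return float(2.0 / (1.0 + math.exp(-t)))
    e = math.exp(t)
    return float(2.0 * e / (1.0 + e))


def _true_class_probability(sample: LogitSample) -> float:
    """sigma(x) for positive samples, 1 - sigma(x) for negatives, stably."""
    x = sample.x if sample.y == 1 else -sample.x
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def polarity_bce_with_logits(
    sample: LogitSample, params: PenaltyParams = PenaltyParams()
) -> float:
    """BCE scaled by the polarity penalty of the true-class probability."""
    return penalty_factor(_true_class_probability(sample), params) * bce_with_logits(sample)


def batch_loss(
    samples: Sequence[LogitSample],
    params: PenaltyParams = PenaltyParams(),
    reduction: str = "mean",
) -> float:
    """Reduce per-sample polarity BCE values over a non-empty batch."""
    if len(samples) == 0:
        raise ValueError("batch_loss requires a non-empty sample list")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    values = [polarity_bce_with_logits(s, params) for s in samples]
    total = float(sum(values))
    return total / len(values) if reduction == "mean" else total


def iou(a: BBox2D, b: BBox2D) -> float:
    """Intersection-over-union of two boxes on the half-open convention."""
    iw = min(a.u_max, b.u_max) - max(a.u_min, b.u_min)
    ih = min(a.v_max, b.v_max) - max(a.v_min, b.v_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return float(inter / (a.area + b.area - inter))


def match_detections(
    pred: Sequence[BBox2D],
    truth: Sequence[BBox2D],
    iou_threshold: float = 0.5,
) -> DetectionCounts:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending score order (unscored boxes rank
    lowest, ties keep input order); each claims the highest-IoU unmatched
    truth box at or above the threshold.  Matched pairs are TPs, leftover
    predictions FPs, leftover truths FNs, so ``tp + fn == len(truth)``.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold!r}")
    order = sorted(
        range(len(pred)),
        key=lambda i: -(pred[i].score if pred[i].score is not None else -math.inf),
    )
    unmatched = set(range(len(truth)))
    tp = 0
    for i in order:
        best_j, best_v = None, -1.0
        for j in sorted(unmatched):  # smallest index wins IoU ties
            v = iou(pred[i], truth[j])
            if v >= iou_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j is not None:
            unmatched.discard(best_j)
            tp += 1
    return DetectionCounts(tp=tp, fp=len(pred) - tp, fn=len(unmatched))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table formatting convention)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def precision_recall(counts: DetectionCounts) -> tuple[float, float]:
    """Precision and recall in percent, rounded half-up to 2 decimals.

    P = 100*TP/(TP+FP), R = 100*TP/(TP+FN).  A zero denominator makes the
    corresponding rate undefined and raises ZeroDivisionError.
    """
    if counts.tp + counts.fp == 0:
        raise ZeroDivisionError("precision undefined: no predictions (tp + fp == 0)")
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("recall undefined: no ground truth (tp + fn == 0)")
    p = 100.0 * counts.tp / (counts.tp + counts.fp)
    r = 100.0 * counts.tp / (counts.tp + counts.fn)
    return round_half_up(p), round_half_up(r)


def f_beta(p: float, r: float, beta: float = 1.0) -> float:
    """F_beta score of precision and recall given as fractions in [0, 1]."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must be fractions in [0, 1]")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    if p == 0.0 and r == 0.0:
        raise ValueError("F_beta undefined when precision and recall are both zero")
    b2 = beta * beta
    return float((1.0 + b2) * p * r / (b2 * p + r))


# ---------------------------------------------------------------------------
# JSON plumbing


def boxes_to_json(boxes: Iterable[BBox2D], path: str | Path) -> None:
    payload = {
        "boxes": [
            {
                "u_min": b.u_min,
                "v_min": b.v_min,
                "u_max": b.u_max,
                "v_max": b.v_max,
                **({"score": b.score} if b.score is not None else {}),
            }
            for b in boxes
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def boxes_from_json(path: str | Path) -> list[BBox2D]:
    payload = json.loads(Path(path).read_text())
    return [
        BBox2D(
            u_min=b["u_min"],
            v_min=b["v_min"],
            u_max=b["u_max"],
            v_max=b["v_max"],
            score=b.get("score"),
        )
        for b in payload["boxes"]
    ]


def metrics_to_json(counts: DetectionCounts, beta: float = 1.0) -> dict:
    """Summary dict {tp, fp, fn, precision_pct, recall_pct, f1}."""
    p_pct, r_pct = precision_recall(counts)
    f1 = round_half_up(f_beta(p_pct / 100.0, r_pct / 100.0, beta))
    return {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision_pct": p_pct,
        "recall_pct": r_pct,
        "f1": f1,
    }
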