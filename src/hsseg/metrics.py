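"""Segmentation quality metrics.

Predicted masks are compared against ground truth with the standard
confusion counts and the derived sensitivity (TPR), specificity (SPC) and
balanced accuracy ACC = (TPR + SPC)/2, all in percent.  Balanced accuracy
is used because the object typically covers a small fraction of the frame,
so plain pixel accuracy would reward trivial all-background predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, UndefinedScoreError

__all__ = ["ConfusionCounts", "Scores", "confusion", "scores", "balanced_accuracy"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Scores:
    """Sensitivity, specificity and balanced accuracy, in percent."""

    tpr: float
    spc: float
    acc: float

    def rounded(self) -> tuple:
        """Integer scores with half-up rounding, as result tables print them."""
        return tuple(int(np.floor(x + 0.5)) for x in (self.tpr, self.spc, self.acc))


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Cross-tabulate two binary masks (foreground = nonzero)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def scores(c: ConfusionCounts) -> Scores:
    """TPR, SPC and ACC in percent; raises if either class is empty."""
    if c.tp + c.fn == 0:
        raise UndefinedScoreError("no positive pixels in truth: TPR undefined")
    if c.tn + c.fp == 0:
        raise UndefinedScoreError("no negative pixels in truth: SPC undefined")
    tpr = 100.0 * c.tp / (c.tp + c.fn)
    spc = 100.0 * c.tn / (c.tn + c.fp)
    return Scores(tpr=tpr, spc=spc, acc=(tpr + spc) / 2.0)


def balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Convenience: balanced accuracy (percent) of a mask against truth."""
    return scores(confusion(pred, truth)).acc
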