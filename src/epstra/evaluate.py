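"""Expert-consensus ground truth and pixel-level segmentation metrics.

Human experts assign every pixel of a field of view to lumen, stroma or
epithelium.  A consensus labeling is built by per-pixel majority vote;
with an even split the tie goes to a fixed priority (epithelium > stroma
> lumen) so the vote is fully deterministic.

Scoring treats epithelium as the positive class.  Lumen-consensus pixels
are eliminated before counting; on the remaining pixels

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    F1          = 2 * precision * recall / (precision + recall)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ags import SegmentationResult

LUMEN, STROMA, EPITHELIUM = 0, 1, 2
#: vote tie-break priority, most preferred first
_TIE_PRIORITY = (EPITHELIUM, STROMA, LUMEN)


@dataclass
class ExpertLabeling:
    """Per-pixel {lumen, stroma, epithelium} labels from one annotator."""

    labels: np.ndarray
    expert_id: str = "expert"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (LUMEN, STROMA, EPITHELIUM)).all():
            raise ValueError("labels must be 0 (lumen), 1 (stroma) or 2 (epithelium)")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ConfusionMetrics:
    """Pixel confusion counts and the derived ratio metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        d = self.precision + self.recall
        return 2.0 * self.precision * self.recall / d if d else 0.0

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(self.tp + other.tp, self.fp + other.fp,
                                self.fn + other.fn, self.tn + other.tn)


def consensus_ground_truth(labelings: list[ExpertLabeling],
                           exclude: str | None = None) -> ExpertLabeling:
    """Per-pixel majority vote over expert labelings.

    ``exclude`` drops one expert by id before voting (used for
    leave-one-out scoring of the experts themselves).  Vote ties resolve
    by the fixed priority epithelium > stroma > lumen.
    """
    pool = [lab for lab in labelings if lab.expert_id != exclude]
    if not pool:
        raise ValueError("need at least one labeling")
    shape = pool[0].labels.shape
    if any(lab.labels.shape != shape for lab in pool):
        raise ValueError("labelings have mismatched extents")
    # counts[i] = votes for _TIE_PRIORITY[i]; argmax takes the first
    # (highest-priority) maximum, which implements the tie rule.
    counts = np.stack([sum((lab.labels == lbl).astype(np.int32) for lab in pool)
                       for lbl in _TIE_PRIORITY])
    winner = np.asarray(_TIE_PRIORITY)[np.argmax(counts, axis=0)]
    return ExpertLabeling(winner, expert_id="consensus")


def score_epithelium(pred: SegmentationResult | np.ndarray,
                     grtr: ExpertLabeling) -> ConfusionMetrics:
    """Score a predicted epithelium mask against consensus ground truth.

    Scoring is restricted to pixels whose consensus label is not lumen;
    on those, the predicted E mask against the consensus E label yields
    TP/FP/FN/TN.  Raises on zero scored pixels.
    """
    pred_e = pred.e_mask if isinstance(pred, SegmentationResult) else np.asarray(pred, dtype=bool)
    if pred_e.shape != grtr.labels.shape:
        raise ValueError("prediction and ground truth extents differ")
    domain = grtr.labels != LUMEN
    if not domain.any():
        raise ValueError("no scored pixels (ground truth is all lumen)")
    gt_e = grtr.labels == EPITHELIUM
    tp = int(np.count_nonzero(pred_e & gt_e & domain))
    fp = int(np.count_nonzero(pred_e & ~gt_e & domain))
    fn = int(np.count_nonzero(~pred_e & gt_e & domain))
    tn = int(np.count_nonzero(~pred_e & ~gt_e & domain))
    return ConfusionMetrics(tp, fp, fn, tn)


def benchmark_methods(predictions: dict[str, list[SegmentationResult | np.ndarray]],
                      truths: list[ExpertLabeling]) -> pd.DataFrame:
    """Pool metrics per method across fields of view.

    ``predictions`` maps method name to one prediction per FOV, aligned
    with ``truths``.  Confusion counts are summed over FOVs before the
    ratios are formed (pooled metrics).
    """
    rows = []
    for method, preds in predictions.items():
        if len(preds) != len(truths):
            raise ValueError(f"{method}: {len(preds)} predictions "
                             f"for {len(truths)} ground truths")
        total = ConfusionMetrics(0, 0, 0, 0)
        for pred, grtr in zip(preds, truths):
            total = total + score_epithelium(pred, grtr)
        rows.append({"method": method, "tp": total.tp, "fp": total.fp,
                     "fn": total.fn, "tn": total.tn,
                     "specificity": total.specificity,
                     "precision": total.precision, "recall": total.recall,
                     "f1": total.f1})
    return pd.DataFrame(rows)
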