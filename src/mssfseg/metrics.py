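"""Segmentation evaluation: confusion counts, Acc/Sen/Spe, and AUC.

Vessel segmentation is a heavily imbalanced binary task (vessels are ~10% of
the field of view), so accuracy alone is uninformative: sensitivity
TP/(TP+FN) measures vessel recall, specificity TN/(TN+FP) background recall,
and the threshold-free AUC summarizes the probability map's ranking quality.
Evaluation is restricted to the FOV disc when a mask is supplied, the usual
convention for fundus benchmarks.  Undefined ratios (zero denominator,
single-class ground truth) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    sen: float
    spe: float
    auc: float
    threshold_used: float = 0.5


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion_counts(
    pred_labels: np.ndarray, gt: np.ndarray, region_mask: np.ndarray | None = None
) -> ConfusionCounts:
    """Pixel confusion counts, optionally restricted to a region mask."""
    p = _as_binary(pred_labels, "pred_labels")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if region_mask is not None:
        sel = np.asarray(region_mask).astype(bool)
        p, g = p[sel], g[sel]
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        tn=int((~p & ~g).sum()),
        fn=int((~p & g).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where the denominator is 0."""
    acc = (c.tp + c.tn) / c.total if c.total else float("nan")
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    return acc, sen, spe


def auc(
    prob: np.ndarray, gt: np.ndarray, region_mask: np.ndarray | None = None
) -> float:
    """Area under the ROC curve of a probability map against binary truth.

    Equals the normalized Mann-Whitney U statistic (ties count 1/2).  Raises
    on single-class ground truth, where the ROC is undefined.
    """
    p = np.asarray(prob, dtype=np.float64)
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if region_mask is not None:
        sel = np.asarray(region_mask).astype(bool)
        p, g = p[sel], g[sel]
    if g.all() or not g.any():
        raise ValueError("AUC undefined: ground truth contains a single class")
    return float(roc_auc_score(g.ravel().astype(int), p.ravel()))


def evaluate_probability_map(
    prob: np.ndarray,
    gt: np.ndarray,
    region_mask: np.ndarray | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report: threshold the map at ``threshold`` for Acc/Sen/Spe, AUC threshold-free."""
    pred = (np.asarray(prob) >= threshold).astype(np.uint8)
    c = confusion_counts(pred, gt, region_mask)
    a, s, sp = metrics_from_counts(c)
    return MetricsReport(acc=a, sen=s, spe=sp, auc=auc(prob, gt, region_mask),
                         threshold_used=threshold)
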