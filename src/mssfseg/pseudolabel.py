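"""Dual-consistency pseudo-label generation.

Given K source-pretrained segmenters and an unlabeled target image, each
model k produces foreground-probability maps on the weak and strong views,
p_k^w and p_k^s.  Pseudo labels come from a *dynamic threshold* T_dyn: the
probability value at the top-gamma% rank of the weak prediction, with gamma
annealed linearly from an upper bound ``a`` down to a lower bound ``b`` over
the adaptation epochs — early on the threshold is permissive, later it
tightens as the model grows confident on the target domain.

Two agreement filters then gate which pixels may supervise the adaptation:

* per-model weak/strong agreement ("inter-domain consistency"): a pixel is
  trusted by model k only if its weak and strong hard labels coincide;
* cross-model unanimity ("intra-domain consistency"): the fused label is the
  common weak label where *all* K models agree, and the ignore value 2
  elsewhere.

All operations are pure, elementwise or rank-based, and array-in/array-out.
Labels are uint8 {0,1}; fused labels uint8 {0,1,2} with 2 = ignore.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

IGNORE_LABEL = 2


def dynamic_gamma(a: float, b: float, total_epoch: int, epoch: int) -> float:
    """Percentage gamma(epoch): linear ramp from ``a`` (epoch 0) down to ``b``.

    gamma(e) = max(a - (a - b) * e / total_epoch, b); requires a >= b >= 0 so
    the threshold rank tightens (never loosens) as adaptation proceeds.
    """
    if a < b:
        raise ValueError("gamma schedule requires a >= b (threshold must tighten)")
    if b < 0:
        raise ValueError("gamma bounds must be >= 0")
    if total_epoch <= 0:
        raise ValueError("total_epoch must be positive")
    if not (0 <= epoch <= total_epoch):
        raise ValueError("epoch must be in [0, total_epoch]")
    if epoch == total_epoch:
        return float(b)  # exact endpoint, no float drift
    return max(a - (a - b) * epoch / total_epoch, b)


def dynamic_threshold(
    prob: np.ndarray, gamma: float, region_mask: np.ndarray | None = None
) -> float:
    """T_dyn: the k-th largest probability, k = max(1, floor(n * gamma / 100)).

    ``n`` is the pixel count of ``region_mask`` (whole map if None).  With
    this nearest-rank convention, thresholding at ``>= T_dyn`` marks exactly
    the top-gamma% pixels as foreground when all values are distinct (more
    under ties).
    """
    if not (0.0 < gamma <= 100.0):
        raise ValueError("gamma must be in (0, 100]")
    vals = np.asarray(prob, dtype=np.float64)
    if region_mask is not None:
        vals = vals[np.asarray(region_mask).astype(bool)]
    vals = vals.ravel()
    n = vals.size
    if n == 0:
        raise ValueError("empty region: cannot compute a dynamic threshold")
    k = max(1, math.floor(n * gamma / 100.0))
    return float(np.partition(vals, n - k)[n - k])


def hard_labels(prob: np.ndarray, t_dyn: float) -> np.ndarray:
    """Binarize a probability map: 1 where prob >= t_dyn, else 0."""
    if not (0.0 <= t_dyn <= 1.0):
        raise ValueError("t_dyn must be in [0, 1]")
    return (np.asarray(prob) >= t_dyn).astype(np.uint8)


def consistency_mask(labels_strong: np.ndarray, labels_weak: np.ndarray) -> np.ndarray:
    """Per-pixel agreement indicator m_k: 1 where the two label maps match."""
    ls = np.asarray(labels_strong)
    lw = np.asarray(labels_weak)
    if ls.shape != lw.shape:
        raise ValueError(f"shape mismatch: {ls.shape} vs {lw.shape}")
    return (ls == lw).astype(np.uint8)


def fuse_labels(weak_labels_per_model: Sequence[np.ndarray]) -> np.ndarray:
    """Cross-model fusion: the unanimous weak label, or ignore (2) on dissent.

    Generalizes the two-model agreement rule to K >= 2 by unanimity: a pixel
    keeps its label only if every model assigns the same one.  Fusion uses
    weak-view labels only.
    """
    if len(weak_labels_per_model) < 2:
        raise ValueError("fusion requires at least 2 models")
    stack = np.stack([np.asarray(m) for m in weak_labels_per_model], axis=0)
    if not np.isin(stack, (0, 1)).all():
        raise ValueError("label maps must be binary")
    agree = (stack == stack[0]).all(axis=0)
    fused = np.where(agree, stack[0], IGNORE_LABEL)
    return fused.astype(np.uint8)
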