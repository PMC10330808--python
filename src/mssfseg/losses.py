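"""Adaptation objective: masked consistency loss + progressive entropy loss.

The consistency loss is a binary cross-entropy between each model's weak-view
probability map and the fused pseudo label, counted only at pixels that pass
both agreement filters (fused label != 2 and the model's weak/strong
consistency mask is 1); every other pixel-model slot contributes zero.  The
mean runs over all K*N slots, so masked-out pixels dilute rather than
renormalize the loss.

The entropy loss is the mean Bernoulli entropy of the weak-view predictions
(-[p log p + (1-p) log(1-p)]), encouraging confident output on *both*
classes; a ``single_term`` variant (-p log p only) is kept behind a flag for
comparison.  Its weight beta ramps linearly from ``a`` up to ``b`` over
training — entropy minimization applied at full strength from the start
collapses an unadapted model onto whatever it currently believes, so the
constraint is phased in as pseudo labels stabilize.

Total objective: Loss = Loss_con + beta * Loss_ent.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .pseudolabel import IGNORE_LABEL

EPS = 1e-7


@dataclass(frozen=True)
class LossBreakdown:
    """One evaluation of the total objective and its parts."""

    loss_con: float
    loss_ent: float
    beta: float
    loss_pro_ent: float
    loss_total: float
    K: int
    N: int
    valid_fraction: float = float("nan")


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)


def _valid_slots(
    fused: np.ndarray, masks_per_model: Sequence[np.ndarray]
) -> list[np.ndarray]:
    fused = np.asarray(fused)
    return [(fused != IGNORE_LABEL) & (np.asarray(m) == 1) for m in masks_per_model]


def consistency_loss(
    prob_weak_per_model: Sequence[np.ndarray],
    fused: np.ndarray,
    masks_per_model: Sequence[np.ndarray],
    region_mask: np.ndarray | None = None,
) -> float:
    """Masked mean binary cross-entropy against the fused pseudo labels.

    Parameters
    ----------
    prob_weak_per_model : K weak-view probability maps (one per source model).
    fused : fused label map in {0, 1, 2}; 2 marks ignored pixels.
    masks_per_model : K weak/strong consistency masks in {0, 1}.
    region_mask : optional evaluation region (e.g. the FOV); pixels outside
        are excluded from both the sum and the normalizing count N.

    Returns the mean over all K*N pixel-model slots, with zero contribution
    from any slot whose pixel is ignored or mask is 0.  Always >= 0.
    """
    K = len(prob_weak_per_model)
    if K != len(masks_per_model):
        raise ValueError("need one consistency mask per model")
    if K == 0:
        raise ValueError("empty model list")
    fused = np.asarray(fused)
    region = (np.asarray(region_mask).astype(bool)
              if region_mask is not None else np.ones(fused.shape, dtype=bool))
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty evaluation region")

    valids = _valid_slots(fused, masks_per_model)
    t = np.where(fused == IGNORE_LABEL, 0, fused).astype(np.float64)
    total = 0.0
    for p_raw, valid in zip(prob_weak_per_model, valids):
        p = _clip(p_raw)
        ce = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
        total += float(ce[valid & region].sum())
    return total / (K * n)


def entropy_loss(
    prob_weak_per_model: Sequence[np.ndarray],
    region_mask: np.ndarray | None = None,
    form: str = "bernoulli",
) -> float:
    """Mean prediction entropy of the weak-view probability maps.

    ``form="bernoulli"`` (default) uses -[p log p + (1-p) log(1-p)], maximal
    ln 2 at p = 0.5 and ~0 at confident predictions of either class;
    ``form="single_term"`` uses -p log p only.
    """
    if len(prob_weak_per_model) == 0:
        raise ValueError("empty model list")
    if form not in ("bernoulli", "single_term"):
        raise ValueError(f"unknown entropy form: {form!r}")
    total = 0.0
    n = None
    for p_raw in prob_weak_per_model:
        p = _clip(p_raw)
        if region_mask is not None:
            p = p[np.asarray(region_mask).astype(bool)]
        if n is None:
            n = p.size
            if n == 0:
                raise ValueError("empty evaluation region")
        if form == "bernoulli":
            h = -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
        else:
            h = -p * np.log(p)
        total += float(h.sum())
    return total / (len(prob_weak_per_model) * n)


def entropy_weight(a: float, b: float, total_epoch: int, epoch: int) -> float:
    """beta(epoch) = min(a + (b - a) * epoch / total_epoch, b): ramp a -> b."""
    if b < a:
        raise ValueError("entropy weight schedule requires b >= a (weight must grow)")
    if a < 0:
        raise ValueError("entropy weights must be >= 0")
    if total_epoch <= 0:
        raise ValueError("total_epoch must be positive")
    if not (0 <= epoch <= total_epoch):
        raise ValueError("epoch must be in [0, total_epoch]")
    if epoch == total_epoch:
        return float(b)  # exact endpoint, no float drift
    return min(a + (b - a) * epoch / total_epoch, b)


def progressive_entropy_loss(loss_ent: float, beta: float) -> float:
    """Entropy loss scaled by the current ramp weight."""
    if loss_ent < 0:
        raise ValueError("entropy loss must be >= 0")
    return beta * loss_ent


def total_loss(
    loss_con: float,
    loss_pro_ent: float,
    *,
    loss_ent: float | None = None,
    beta: float | None = None,
    K: int = 0,
    N: int = 0,
    valid_fraction: float = float("nan"),
) -> LossBreakdown:
    """Combine the components into the final objective Loss = Loss_con + beta*Loss_ent."""
    if not (np.isfinite(loss_con) and np.isfinite(loss_pro_ent)):
        raise ValueError("loss components must be finite")
    return LossBreakdown(
        loss_con=float(loss_con),
        loss_ent=float(loss_ent) if loss_ent is not None else float("nan"),
        beta=float(beta) if beta is not None else float("nan"),
        loss_pro_ent=float(loss_pro_ent),
        loss_total=float(loss_con + loss_pro_ent),
        K=K,
        N=N,
        valid_fraction=valid_fraction,
    )
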