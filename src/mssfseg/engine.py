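"""Training engines: source pretraining, source-free adaptation, ensemble inference.

The adaptation setting is multi-source and source-free (MSSF): K segmenters,
each pretrained on its own labeled source domain, are adapted to an
*unlabeled* target domain without ever revisiting source data.  Each epoch:

1. anneal the pseudo-label threshold percentage gamma and the entropy weight
   beta according to their linear schedules;
2. for every target image, build a weak/strong augmented pair sharing one
   geometric transform; run every model on both views;
3. per model, binarize the weak prediction at the dynamic threshold, reuse
   the same threshold on the strong view, and keep only pixels where the two
   hard labels agree (the per-model consistency mask);
4. fuse the weak labels across models by unanimity (dissenting pixels get
   the ignore label 2);
5. take one Adam step on all K models jointly, on the masked consistency
   loss plus the beta-weighted entropy loss.

Ablation switches reproduce the reduced variants: the *baseline* drops all
three components and self-trains on the ensemble-mean prediction thresholded
at 0.5; *method-a* adds the weak/strong (inter-domain) consistency;
*method-b* adds cross-model (intra-domain) fusion; *method-c* adds the
progressive entropy loss.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from collections.abc import Sequence

import numpy as np

from .augment import AugmentConfig, apply_geometry, make_augmented_pair, normalize_intensity
from .losses import (LossBreakdown, consistency_loss, entropy_loss, entropy_weight,
                     progressive_entropy_loss, total_loss, _clip)
from .model import Adam, ModelConfig, SegmentationModel
from .pseudolabel import (IGNORE_LABEL, consistency_mask, dynamic_gamma,
                          dynamic_threshold, fuse_labels, hard_labels)


@dataclass
class Sample:
    """One image with optional ground-truth vessel mask and FOV mask."""

    image: np.ndarray
    mask: np.ndarray | None = None
    fov: np.ndarray | None = None


@dataclass
class SourceModelBundle:
    """K source-pretrained segmenters with their domain names."""

    models: list[SegmentationModel]
    domain_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.models) < 1:
            raise ValueError("bundle needs at least one model")
        if len(self.models) != len(self.domain_ids):
            raise ValueError("one domain id per model")

    @property
    def K(self) -> int:
        return len(self.models)

    def copy(self) -> "SourceModelBundle":
        return SourceModelBundle([m.copy() for m in self.models], list(self.domain_ids))


@dataclass(frozen=True)
class PretrainConfig:
    """Supervised source training settings (plain BCE on labeled phantoms)."""

    learning_rate: float = 1e-2
    epochs: int = 30
    batch_size: int = 4
    label_smoothing: float = 0.0
    seed: int = 0
    model: ModelConfig = ModelConfig()
    augment: AugmentConfig = AugmentConfig(gray_max=0.0, jitter=0.0)


@dataclass(frozen=True)
class AdaptationConfig:
    """MSSF adaptation settings; defaults follow the adaptation protocol
    (Adam, lr 2e-5, batch 2, 10 epochs) with config-exposed schedules."""

    learning_rate: float = 2e-5
    batch_size: int = 2
    total_epoch: int = 10
    gamma_schedule: tuple[float, float] = (15.0, 10.0)
    beta_schedule: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    use_inter_cc: bool = True
    use_intra_cc: bool = True
    use_pel: bool = True
    entropy_form: str = "bernoulli"
    augment: AugmentConfig = AugmentConfig()

    def __post_init__(self) -> None:
        a, b = self.gamma_schedule
        if a < b:
            raise ValueError("gamma schedule must decrease: need a >= b")
        ba, bb = self.beta_schedule
        if bb < ba:
            raise ValueError("beta schedule must increase: need b >= a")
        if self.batch_size < 1 or self.total_epoch < 0:
            raise ValueError("batch_size >= 1 and total_epoch >= 0 required")


ABLATION_PRESETS = {
    "baseline": dict(use_inter_cc=False, use_intra_cc=False, use_pel=False),
    "method-a": dict(use_inter_cc=True, use_intra_cc=False, use_pel=False),
    "method-b": dict(use_inter_cc=True, use_intra_cc=True, use_pel=False),
    "method-c": dict(use_inter_cc=True, use_intra_cc=True, use_pel=True),
}


def ablation_config(name: str, base: AdaptationConfig = AdaptationConfig()) -> AdaptationConfig:
    """An AdaptationConfig with the switch pattern of one ablation variant."""
    if name not in ABLATION_PRESETS:
        raise ValueError(f"unknown ablation variant {name!r}; "
                         f"choose from {sorted(ABLATION_PRESETS)}")
    return replace(base, **ABLATION_PRESETS[name])


@dataclass
class AdaptationLog:
    """Per-iteration loss rows plus per-epoch mean breakdowns."""

    rows: list[dict] = field(default_factory=list)
    epoch_means: list[LossBreakdown] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            Path(path).write_text("")
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.rows[0].keys()))
            writer.writeheader()
            writer.writerows(self.rows)


# ---------------------------------------------------------------------------
# source pretraining
# ---------------------------------------------------------------------------

def pretrain_source(
    samples: Sequence[Sample],
    config: PretrainConfig = PretrainConfig(),
    domain_id: str = "",
) -> tuple[SegmentationModel, list[float]]:
    """Train one segmenter on a labeled source domain with binary cross-entropy.

    Geometric augmentation (random 90-degree rotation + flips) is resampled
    every epoch; intensity normalization runs over the FOV.  Returns the model
    and the per-epoch mean training loss.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty training dataset")
    for s in samples:
        if s.mask is None:
            raise ValueError("pretraining requires ground-truth masks")

    rng = np.random.default_rng(config.seed)
    model = SegmentationModel(config.model, seed=int(rng.integers(2**31)),
                              domain_id=domain_id)
    opt = Adam(model, config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = None
            for idx in batch:
                s = samples[idx]
                pair = make_augmented_pair(s.image, int(rng.integers(2**31)),
                                           config.augment, s.fov)
                geo = pair.geometric_record
                y = apply_geometry(s.mask, geo).astype(np.float64)
                ls = config.label_smoothing
                y = y * (1.0 - 2.0 * ls) + ls  # soft targets keep logits unsaturated
                region = (apply_geometry(s.fov, geo).astype(bool)
                          if s.fov is not None else np.ones(y.shape, dtype=bool))
                n = int(region.sum())
                p, cache = model.forward(pair.weak_image)
                pc = _clip(p)
                bce = -(y * np.log(pc) + (1 - y) * np.log(1 - pc))
                losses.append(float(bce[region].sum()) / n)
                dz2 = np.where(region, p - y, 0.0) / n
                g = model.backward(cache, dz2)
                grads = g if grads is None else {k: grads[k] + g[k] for k in g}
            opt.step({k: v / len(batch) for k, v in grads.items()})
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# source-free adaptation
# ---------------------------------------------------------------------------

def _pseudo_labels_for_image(models, pair, region, gamma, cfg):
    """Per-model weak/strong labels + masks and the fused target for one image.

    Returns (probs_weak, caches, masks, fused) where ``fused`` is uint8
    {0,1,2}.  With intra-domain fusion off, the target is the ensemble-mean
    prediction thresholded (dynamically when inter CC is on, else at 0.5) and
    no pixel is ignored.
    """
    probs_w, caches, labels_w, masks = [], [], [], []
    for model in models:
        p_w, cache = model.forward(pair.weak_image)
        probs_w.append(p_w)
        caches.append(cache)
        if cfg.use_inter_cc:
            t_dyn = dynamic_threshold(p_w, gamma, region)
            l_w = hard_labels(p_w, t_dyn)
            p_s = model.predict(pair.strong_image)
            l_s = hard_labels(p_s, t_dyn)
            masks.append(consistency_mask(l_s, l_w))
        else:
            l_w = hard_labels(p_w, 0.5)
            masks.append(np.ones(l_w.shape, dtype=np.uint8))
        labels_w.append(l_w)

    if cfg.use_intra_cc:
        fused = fuse_labels(labels_w)
    else:
        mean_p = np.mean(probs_w, axis=0)
        thr = dynamic_threshold(mean_p, gamma, region) if cfg.use_inter_cc else 0.5
        fused = hard_labels(mean_p, thr)
    return probs_w, caches, masks, fused


def adapt(
    bundle: SourceModelBundle,
    target_samples: Sequence[Sample],
    config: AdaptationConfig = AdaptationConfig(),
) -> tuple[SourceModelBundle, AdaptationLog]:
    """Adapt K source models to unlabeled target images (ground truth unused).

    The input bundle is left untouched; a copied, adapted bundle is returned
    together with the training log.  All K models take one joint Adam step
    per batch on Loss = Loss_con + beta * Loss_ent.
    """
    if config.use_intra_cc and bundle.K < 2:
        raise ValueError("intra-domain consistency requires K >= 2 source models")
    target_samples = list(target_samples)
    if not target_samples:
        raise ValueError("empty target dataset")

    adapted = bundle.copy()
    rng = np.random.default_rng(config.seed)
    opts = [Adam(m, config.learning_rate) for m in adapted.models]
    log = AdaptationLog()
    K = adapted.K

    for epoch in range(config.total_epoch):
        ga, gb = config.gamma_schedule
        gamma = dynamic_gamma(ga, gb, config.total_epoch, epoch) if config.use_inter_cc else None
        ba, bb = config.beta_schedule
        beta = (entropy_weight(ba, bb, config.total_epoch, epoch)
                if config.use_pel else 0.0)
        order = rng.permutation(len(target_samples))
        epoch_rows: list[LossBreakdown] = []

        for it, start in enumerate(range(0, len(order), config.batch_size)):
            batch = order[start : start + config.batch_size]
            grads = [None] * K
            b_con, b_ent, b_valid = [], [], []
            for idx in batch:
                s = target_samples[idx]
                pair = make_augmented_pair(s.image, int(rng.integers(2**31)),
                                           config.augment, s.fov)
                region = (apply_geometry(s.fov, pair.geometric_record).astype(bool)
                          if s.fov is not None
                          else np.ones(s.image.shape[:2], dtype=bool))
                n = int(region.sum())
                probs_w, caches, masks, fused = _pseudo_labels_for_image(
                    adapted.models, pair, region, gamma, config)

                l_con = consistency_loss(probs_w, fused, masks, region)
                l_ent = entropy_loss(probs_w, region, config.entropy_form)
                if not (np.isfinite(l_con) and np.isfinite(l_ent)):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: con={l_con}, ent={l_ent}")
                b_con.append(l_con)
                b_ent.append(l_ent)
                t = np.where(fused == IGNORE_LABEL, 0, fused).astype(np.float64)
                valid_any = 0
                for k in range(K):
                    valid = (fused != IGNORE_LABEL) & (masks[k] == 1) & region
                    valid_any += int(valid.sum())
                    dz2 = np.where(valid, probs_w[k] - t, 0.0) / (K * n)
                    if config.use_pel and beta > 0:
                        p = _clip(probs_w[k])
                        dent = p * (1 - p) * np.log((1 - p) / p)
                        dz2 = dz2 + beta * np.where(region, dent, 0.0) / (K * n)
                    g = adapted.models[k].backward(caches[k], dz2)
                    grads[k] = g if grads[k] is None else {
                        key: grads[k][key] + g[key] for key in g}
                b_valid.append(valid_any / (K * n))

            for k in range(K):
                opts[k].step({key: v / len(batch) for key, v in grads[k].items()})

            mean_con = float(np.mean(b_con))
            mean_ent = float(np.mean(b_ent))
            pro_ent = progressive_entropy_loss(mean_ent, beta)
            bd = total_loss(mean_con, pro_ent, loss_ent=mean_ent, beta=beta,
                            K=K, N=n, valid_fraction=float(np.mean(b_valid)))
            epoch_rows.append(bd)
            log.rows.append({
                "epoch": epoch, "iteration": it, "gamma": gamma if gamma is not None else "",
                "beta": beta, "loss_con": bd.loss_con, "loss_ent": bd.loss_ent,
                "loss_total": bd.loss_total, "valid_fraction": bd.valid_fraction,
            })

        log.epoch_means.append(LossBreakdown(
            loss_con=float(np.mean([r.loss_con for r in epoch_rows])),
            loss_ent=float(np.mean([r.loss_ent for r in epoch_rows])),
            beta=beta,
            loss_pro_ent=float(np.mean([r.loss_pro_ent for r in epoch_rows])),
            loss_total=float(np.mean([r.loss_total for r in epoch_rows])),
            K=K, N=epoch_rows[-1].N,
            valid_fraction=float(np.mean([r.valid_fraction for r in epoch_rows])),
        ))
    return adapted, log


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict_ensemble(
    bundle: SourceModelBundle, image: np.ndarray, fov: np.ndarray | None = None
) -> np.ndarray:
    """Unweighted mean of the K models' probability maps on the normalized image."""
    norm = normalize_intensity(image, fov)
    return np.mean([m.predict(norm) for m in bundle.models], axis=0)


def evaluate_ensemble(bundle: SourceModelBundle, samples: Sequence[Sample],
                      threshold: float = 0.5):
    """Mean MetricsReport of the ensemble over labeled samples (FOV-restricted)."""
    from .metrics import MetricsReport, evaluate_probability_map

    reports = []
    for s in samples:
        if s.mask is None:
            raise ValueError("evaluation requires ground-truth masks")
        prob = predict_ensemble(bundle, s.image, s.fov)
        reports.append(evaluate_probability_map(prob, s.mask, s.fov, threshold))
    return MetricsReport(
        acc=float(np.mean([r.acc for r in reports])),
        sen=float(np.mean([r.sen for r in reports])),
        spe=float(np.mean([r.spe for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        threshold_used=threshold,
    ), reports
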