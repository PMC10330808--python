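# Methods

This note documents the models, parameters, numerical conventions and design
choices behind `mssfseg`, and what the synthetic experiments do and do not
demonstrate.

## Setting and assumptions

K ≥ 2 binary segmenters, each pretrained on its own labeled source domain,
are adapted to an unlabeled target domain; source images are never revisited
(source-free).  The method assumes (i) every model outputs a per-pixel
foreground probability in (0,1) on the target images, (ii) the domains share
the task semantics (vessels on a retina disc) and differ photometrically,
and (iii) the source models' errors on the target are not perfectly
correlated — cross-model agreement carries information only then.

## Pseudo-label generation

**Dynamic threshold.** T_dyn is the nearest-rank top-γ% value of the weak
prediction: the k-th largest probability with k = max(1, ⌊n·γ/100⌋), n the
pixel count of the pooling region.  This convention makes the positive count
exactly k for distinct values, which the tests exploit.  Pooling is per
image, per model, per epoch, over the FOV when a FOV mask exists (whole
image otherwise).  Thresholding uses ≥, so a pixel exactly at T_dyn is
foreground.  The strong view is binarized with the *same* T_dyn as the weak
view of that image/model; T_dyn is never computed from a strong prediction.

**γ schedule.** γ(e) = max(a − (a−b)·e/total_epoch, b), non-increasing, with
exact endpoints (the final epoch returns b exactly rather than through the
float expression).  Defaults a = 15, b = 10 (percent).  Rationale: hard
pseudo-positives are useful exactly when their count tracks the true
foreground prevalence.  Phantom vessels occupy 5–15% of the FOV (mean ≈
10%), and the operating points published for adapted vessel segmenters on
fundus benchmarks imply a predicted-positive fraction of roughly 1.0–1.4×
the vessel prior; the schedule therefore starts at 1.5× the prior (wide net
while the models are still miscalibrated on the target) and anneals to the
prior.  Setting the bounds an order of magnitude higher (e.g. marking half
the FOV as vessel) floods training with false positives on a ~10%-prevalence
task.  A configuration with a < b is rejected: the threshold rank must
tighten, never loosen.

**Filters.** The per-model consistency mask is the elementwise equality of
the weak and strong hard labels.  Cross-model fusion is unanimity over all K
weak-label maps — agreement keeps the common label, any dissent yields the
ignore value 2.  Unanimity generalizes the two-model rule to K > 2 and is
monotone: adding a model can only shrink the valid set (property-tested).

## Losses

Binary cross-entropy against the fused label, −[t log p + (1−t) log(1−p)],
averaged over all K·N pixel-model slots with zero contribution where t = 2
or m = 0; masked-out slots dilute rather than renormalize, so the loss value
reflects the usable supervision density.  N is the pixel count of the
current batch's evaluation region (mini-batch optimization requires
per-batch evaluation; the epoch mean is the running mean over batches).

The entropy term defaults to the full Bernoulli entropy
−[p log p + (1−p) log(1−p)], which is minimized by confidence on *either*
class; a literal single-term variant −p log p is available as
`entropy_form="single_term"` for comparison, but it is asymmetric (free at
p→0, maximal near p≈0.37) and does not reward confident foreground, so it is
not the default.  The weight β follows min(a + (b−a)·e/total_epoch, b),
non-decreasing, defaults 0 → 1: entropy minimization applied at full
strength from epoch 0 collapses a miscalibrated model onto its current
beliefs before pseudo-labels stabilize.

Numerical conventions: probabilities clipped to [1e-7, 1 − 1e-7] before any
log; logits clipped to ±30 before the sigmoid so outputs stay in the open
interval; total loss is rejected if non-finite (the adaptation loop aborts
with a diagnostic rather than silently averaging NaN).

## Backbone and optimization

The segmenter is a pixelwise MLP over a fixed filter bank: per scale
σ ∈ sigmas, the Gaussian-smoothed luminance, the Gaussian gradient
magnitude, and the σ²-normalized leading Hessian eigenvalue (positive on
dark ridges — the classic curvilinear-structure detector), plus the three
raw normalized channels; every feature map is z-scored per image.  A tanh
hidden layer (default width 128) feeds a sigmoid output.  Gradients are
derived by hand (two affine layers, two pointwise nonlinearities) and
verified against finite differences in the tests.  The filter bank is
frozen; only the MLP trains.

The adaptation machinery never inspects the architecture: any object with
`forward`/`backward`/`params` in the same contract would do.  Each source
model may use its own scale set — the shipped study gives domain A
(1, 2, 4) px and domain B (0.75, 1.5, 3) px — because cross-model fusion
needs decorrelated errors, and two models over an identical frozen filter
bank err almost identically.

Pretraining: plain BCE on labeled phantoms, Adam lr 1e-2, 30 epochs,
batch 4, geometric augmentation resampled per epoch.  An optional
label-smoothing parameter exists but defaults to 0: smoothing caps the
attainable confidence, which inflates the entropy term and lets the β ramp
dominate the adaptation loss trajectory.

Adaptation: Adam lr 2e-5, batch 2, 10 epochs (the standard protocol for this
method family); β₁/β₂ at the conventional 0.9/0.999.  All K models take one
joint step per batch on the summed objective.  Schedules advance per epoch,
not per iteration.  Augmentation is resampled every epoch.  `total_epoch=0`
returns a bitwise-identical copy of the bundle.  Deterministic, single-
worker execution is the default and the only mode used by tests.

Ablation presets map to switch patterns: baseline = no dynamic threshold
(fixed 0.5), ensemble-mean pseudo label, no masks, no entropy; method-a
adds the weak/strong filter + dynamic threshold; method-b adds unanimity
fusion; method-c adds the entropy ramp.  With fusion off, the target is the
ensemble-mean probability thresholded (dynamically if the weak/strong
constraint is on, else at 0.5) and no pixel is ignored.

## The phantom study

`fixtures.build_fixture` pins the desk-scale conditions: 64×64 phantoms,
vessel fraction 5–15% of the FOV, 20 labeled images per source domain, 20
unlabeled target images for adaptation, 10 labeled for evaluation, all
derived from one seed.  Phantoms are recursive quadratic-Bézier vessel trees
(per-level width decay, random branch angles, rejection-sampled to the
density range with a 20-draw budget) on a retina-like background with radial
falloff and low-frequency blotches.  Domain styles are photometric only:
gamma, brightness, per-channel mix, Gaussian blur, sensor noise.  The target
style (gamma 0.8, brightness 1.15, blur 1.3 px, noise sd 0.06) is calibrated
so that source-pretrained ensembles transfer at AUC ≈ 0.93–0.96 and
sensitivity ≈ 0.45–0.55 — the regime reported for real cross-device fundus
transfer — rather than at the near-ceiling AUC a milder shift produces.

What the phantoms do **not** emulate: pathology (lesions, exudates),
resolution differences between cohorts, annotation ambiguity on thin
vessels, optic disc and macula structure, and spatially correlated label
noise.  Passing tests therefore demonstrate the *mechanics and direction*
of the method (pseudo-label precision gains from fusion, sensitivity gains
from the annealed threshold, the ablation ordering) at desk scale — not
clinical-grade segmentation quality.

## Measured behaviour and limitations

Across seeded end-to-end runs the adaptation objective falls monotonically
in the mean, target sensitivity rises for every dynamic-threshold variant,
and the ablation ordering method-c ≥ method-a ≥ baseline holds on
sensitivity.  Two trade-offs are consistently visible, and both are
properties of the method rather than implementation artifacts:

* **Sensitivity is bought with specificity.**  The annealed rank threshold
  marks more pixels vessel than the models would at 0.5, so recall rises
  while background precision dips slightly — visible in the worked example
  (Spe 0.9796 → 0.9775).
* **Ranking quality is not guaranteed to improve.**  Hard-label
  self-training hardens the ~15% of pseudo-positives that are wrong; the
  pure self-sharpening baseline variant typically *gains* a little AUC while
  the dynamic-threshold variants spend a comparable amount (order 1e-4 to
  1e-3 here) to buy their sensitivity.  Users for whom AUC is the primary
  endpoint should prefer the baseline preset or a stricter γ.

Other limitations: the frozen filter bank cannot perform feature-level
adaptation (only the head re-weights evidence), unanimity fusion discards
exactly the pixels where models could teach each other, and all schedules
assume the 10-epoch protocol — longer runs would need re-tuned bounds.
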