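"""Synthetic fundus phantoms: vessel trees, domain styles, mock predictors.

Real fundus photographs show a branching, curvilinear vascular tree on a
disc-shaped retina (the field of view, FOV) whose appearance differs between
acquisition devices — brightness, gamma, colour balance, blur and sensor
noise all shift between cohorts such as DRIVE, CHASEDB1 and IOSTAR.  This
module generates miniature stand-ins for those data: a ground-truth vessel
mask drawn as recursive quadratic Bézier branches, a reddish retina
background with a radial intensity falloff and low-frequency blotches, and a
:class:`DomainStyle` photometric transform that emulates the cross-device
shift.  A :class:`MockPredictorSpec` additionally fabricates per-pixel
probability maps with a controlled error rate, so pseudo-label machinery can
be tested without training any model.

Nothing here aims at photo-realism; the phantoms exist so that every
downstream stage (augmentation, pseudo-labelling, adaptation, evaluation)
runs and is testable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class InfeasiblePhantomError(RuntimeError):
    """Raised when no vessel tree hits the target density within the retry budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic fundus phantom.

    Parameters
    ----------
    image_size : int
        Side length in pixels of the square image (>= 32).
    fov_radius_frac : float
        Radius of the circular field of view as a fraction of half the image
        width, in (0, 1].
    n_trees : int
        Number of vessel root branches seeded on the FOV boundary.
    max_depth : int
        Branching depth of each tree.
    root_width_px : float
        Stroke width of a root branch, in pixels.
    width_decay : float
        Multiplicative width decay per branching level, in (0, 1).
    target_vessel_frac_range : tuple of float
        (lo, hi) admissible vessel-pixel fraction of the FOV; trees are
        redrawn until the drawn fraction lands inside, 0 <= lo < hi < 0.5.
    """

    image_size: int = 128
    fov_radius_frac: float = 0.94
    n_trees: int = 4
    max_depth: int = 5
    root_width_px: float = 3.0
    width_decay: float = 0.82
    target_vessel_frac_range: tuple[float, float] = (0.06, 0.14)

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 < self.fov_radius_frac <= 1.0):
            raise ValueError("fov_radius_frac must be in (0, 1]")
        if not (0.0 < self.width_decay < 1.0):
            raise ValueError("width_decay must be in (0, 1)")
        lo, hi = self.target_vessel_frac_range
        if not (0.0 <= lo < hi < 0.5):
            raise ValueError("target_vessel_frac_range must satisfy 0 <= lo < hi < 0.5")
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


@dataclass(frozen=True)
class DomainStyle:
    """Photometric appearance of one acquisition domain.

    The identity style ``DomainStyle()`` maps any image to itself exactly.
    """

    gamma: float = 1.0
    brightness_scale: float = 1.0
    channel_mix: tuple[float, float, float] = (1.0, 1.0, 1.0)
    blur_sigma: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.brightness_scale <= 0:
            raise ValueError("gamma and brightness_scale must be > 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")


@dataclass(frozen=True)
class MockPredictorSpec:
    """A fake segmenter: i.i.d. per-pixel label flips at a fixed confidence.

    With probability ``1 - flip_rate`` a pixel's probability map assigns
    ``confidence`` to the true class, otherwise to the wrong class.
    """

    flip_rate: float = 0.2
    confidence: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_rate <= 1.0):
            raise ValueError("flip_rate must be in [0, 1]")
        if not (0.5 < self.confidence <= 1.0):
            raise ValueError("confidence must be in (0.5, 1]")


def _fov_disc(size: int, radius_frac: float) -> np.ndarray:
    c = (size - 1) / 2.0
    r = radius_frac * size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= r**2).astype(np.uint8)


def _stamp_segment(canvas: np.ndarray, p0, p1, p2, width: float) -> None:
    """Rasterize a quadratic Bézier stroke of the given width onto a bool canvas."""
    n = canvas.shape[0]
    # sample density proportional to the control-polygon length
    approx_len = np.hypot(*(p1 - p0)) + np.hypot(*(p2 - p1))
    steps = max(int(2 * approx_len), 8)
    t = np.linspace(0.0, 1.0, steps)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    rad = max(width / 2.0, 0.5)
    ri = int(np.ceil(rad))
    offs = np.mgrid[-ri : ri + 1, -ri : ri + 1].reshape(2, -1).T
    offs = offs[np.hypot(offs[:, 0], offs[:, 1]) <= rad]
    cells = np.rint(pts).astype(int)[:, None, :] + offs[None, :, :]
    cells = cells.reshape(-1, 2)
    keep = (cells[:, 0] >= 0) & (cells[:, 0] < n) & (cells[:, 1] >= 0) & (cells[:, 1] < n)
    cells = cells[keep]
    canvas[cells[:, 0], cells[:, 1]] = True


def _grow_tree(canvas, rng, pos, direction, width, depth, spec: PhantomSpec) -> None:
    if depth > spec.max_depth or width < 0.4:
        return
    n = spec.image_size
    seg_len = rng.uniform(0.18, 0.30) * n * (0.85**depth)
    bend = rng.normal(0.0, 0.5)
    d0 = np.array([np.cos(direction), np.sin(direction)])
    d1 = np.array([np.cos(direction + bend), np.sin(direction + bend)])
    p0 = pos
    p1 = pos + d0 * seg_len * 0.5
    p2 = pos + (d0 + d1) / 2 * seg_len
    _stamp_segment(canvas, p0, p1, p2, width)
    # branch: continue the main axis and fork a child at a random angle
    new_dir = direction + bend * 0.6
    _grow_tree(canvas, rng, p2, new_dir, width * spec.width_decay, depth + 1, spec)
    if rng.random() < 0.85:
        fork = new_dir + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0)
        _grow_tree(canvas, rng, p2, fork, width * spec.width_decay, depth + 1, spec)


def _draw_vessels(spec: PhantomSpec, rng: np.random.Generator, fov: np.ndarray) -> np.ndarray:
    n = spec.image_size
    canvas = np.zeros((n, n), dtype=bool)
    c = (n - 1) / 2.0
    r = spec.fov_radius_frac * n / 2.0
    for _ in range(spec.n_trees):
        # roots on the FOV rim, pointing inward like vessels leaving the optic disc
        theta = rng.uniform(0, 2 * np.pi)
        pos = np.array([c + 0.85 * r * np.sin(theta), c + 0.85 * r * np.cos(theta)])
        inward = theta + np.pi + rng.normal(0.0, 0.4)
        direction = np.arctan2(np.sin(inward), np.cos(inward))
        _grow_tree(canvas, rng, pos, direction, spec.root_width_px, 0, spec)
    return (canvas & fov.astype(bool)).astype(np.uint8)


def generate_phantom(
    spec: PhantomSpec, seed: int, max_retries: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one synthetic fundus image with vessel and FOV masks.

    Returns
    -------
    image : (H, W, 3) float64 in [0, 1]
    gt_mask : (H, W) uint8 in {0, 1}, subset of ``fov_mask``
    fov_mask : (H, W) uint8 in {0, 1}, a filled disc

    Vessel trees are redrawn (rejection sampling, ``max_retries`` attempts)
    until the vessel fraction of the FOV lands inside
    ``spec.target_vessel_frac_range``; identical ``(spec, seed)`` give
    bit-identical outputs.

    Raises
    ------
    InfeasiblePhantomError
        If no draw within the retry budget meets the density range.
    """
    rng = np.random.default_rng(seed)
    n = spec.image_size
    fov = _fov_disc(n, spec.fov_radius_frac)
    n_fov = int(fov.sum())
    lo, hi = spec.target_vessel_frac_range

    gt = None
    for _ in range(max_retries):
        cand = _draw_vessels(spec, rng, fov)
        frac = cand.sum() / n_fov
        if lo <= frac <= hi:
            gt = cand
            break
    if gt is None:
        raise InfeasiblePhantomError(
            f"no vessel draw hit fraction range ({lo}, {hi}) in {max_retries} tries"
        )

    # retina background: warm base colour, radial falloff, low-frequency blotches
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c) / (spec.fov_radius_frac * n / 2.0)
    radial = 1.0 - 0.35 * np.clip(rr, 0, 1) ** 2
    blotch = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 10.0)
    blotch = 0.08 * blotch / (blotch.std() + 1e-12)
    lum = np.clip(radial + blotch, 0.0, 1.2)

    base = np.array([0.82, 0.48, 0.30])  # fundus-like orange/red
    image = lum[:, :, None] * base[None, None, :]
    image[gt.astype(bool)] *= 0.45  # vessels are dark
    image *= fov[:, :, None]  # black outside the eye
    image = np.clip(image, 0.0, 1.0)
    return image, gt, fov


def apply_domain_style(image: np.ndarray, style: DomainStyle, seed: int = 0) -> np.ndarray:
    """Apply a photometric domain shift to an image in [0, 1].

    Order of operations: gamma, brightness, per-channel mix, Gaussian blur,
    additive Gaussian noise, clip to [0, 1].  Geometry is untouched, so any
    mask registered to the input stays valid.  The identity style returns the
    input exactly.
    """
    out = np.asarray(image, dtype=np.float64)
    if style.gamma != 1.0:
        out = np.clip(out, 0.0, None) ** style.gamma
    if style.brightness_scale != 1.0:
        out = out * style.brightness_scale
    if tuple(style.channel_mix) != (1.0, 1.0, 1.0):
        out = out * np.asarray(style.channel_mix, dtype=np.float64)[None, None, :]
    if style.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=(style.blur_sigma, style.blur_sigma, 0))
    if style.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, style.noise_sd, size=out.shape)
    if out is image:
        return image
    return np.clip(out, 0.0, 1.0)


def mock_probability_map(gt_mask: np.ndarray, spec: MockPredictorSpec) -> np.ndarray:
    """Fabricate a foreground-probability map from ground truth.

    Each pixel independently keeps its true label with probability
    ``1 - flip_rate``; the (possibly flipped) label then receives probability
    ``confidence`` and the other class ``1 - confidence``.  Reproducible from
    ``spec.seed``.
    """
    gt = np.asarray(gt_mask).astype(bool)
    rng = np.random.default_rng(spec.seed)
    flipped = rng.random(gt.shape) < spec.flip_rate
    label = gt ^ flipped
    return np.where(label, spec.confidence, 1.0 - spec.confidence)


# Styles loosely emulating the photometric spread between public fundus sets:
# a neutral reference, a dimmer/greener one, and a bright high-contrast one.
DEFAULT_STYLES: dict[str, DomainStyle] = {
    "domainA": DomainStyle(gamma=1.0, brightness_scale=1.0, channel_mix=(1.0, 1.0, 1.0),
                           blur_sigma=0.0, noise_sd=0.01),
    "domainB": DomainStyle(gamma=1.3, brightness_scale=0.85, channel_mix=(0.95, 1.1, 0.9),
                           blur_sigma=0.6, noise_sd=0.02),
    "target": DomainStyle(gamma=0.8, brightness_scale=1.15, channel_mix=(1.1, 0.9, 1.05),
                          blur_sigma=1.3, noise_sd=0.06),
}
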