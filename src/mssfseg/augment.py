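"""Paired weak/strong augmentation with shared geometry.

Self-training on unlabeled target images compares, pixel by pixel, the
predictions a source model makes on two views of the same image: a *weak*
view (intensity normalization + random rotation + random flip) and a
*strong* view that additionally perturbs photometry (random gray-scale blend
and per-channel color jitter).  Pixelwise comparison is only meaningful if
pixel i in one view is the same retinal location as pixel i in the other, so
both views share one :class:`GeometricRecord`; only photometry differs.

Rotations default to multiples of 90 degrees, which are exact on the pixel
grid; arbitrary angles with bilinear interpolation sit behind a config flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GeometricRecord:
    """Rotation + flips applied to a view; invertible for 90-degree multiples."""

    angle_deg: float = 0.0
    flip_h: bool = False
    flip_v: bool = False

    @property
    def is_exact(self) -> bool:
        return float(self.angle_deg) % 90.0 == 0.0

    def inverse(self) -> "GeometricRecord":
        """The record undoing this one (dihedral group, found by probe).

        Only defined for 90-degree-multiple rotations, where the transform is
        an exact signed permutation of the pixel grid.
        """
        if not self.is_exact:
            raise ValueError("only 90-degree-multiple rotations are exactly invertible")
        probe = np.arange(6.0).reshape(2, 3)
        fwd = apply_geometry(probe, self)
        for angle in (0.0, 90.0, 180.0, 270.0):
            for fh in (False, True):
                for fv in (False, True):
                    cand = GeometricRecord(angle_deg=angle, flip_h=fh, flip_v=fv)
                    if np.array_equal(apply_geometry(fwd, cand), probe):
                        return cand
        raise AssertionError("unreachable: dihedral group is closed under inversion")


@dataclass(frozen=True)
class PhotometricRecord:
    """Strong-view photometric parameters (gray blend weight, RGB jitter factors)."""

    gray_weight: float = 0.0
    jitter: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling ranges for the augmentation pipeline.

    gray_max is the upper bound of the uniform gray-blend weight, jitter the
    half-width of the uniform per-channel multiplicative factor range
    (factors ~ U(1-jitter, 1+jitter)).
    """

    rotate: bool = True
    flip: bool = True
    arbitrary_rotation: bool = False
    gray_max: float = 1.0
    jitter: float = 0.4


@dataclass(frozen=True)
class AugmentedPair:
    weak_image: np.ndarray
    strong_image: np.ndarray
    geometric_record: GeometricRecord
    photometric_record: PhotometricRecord


def normalize_intensity(image: np.ndarray, fov_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-channel z-score normalization over the FOV region (whole image if none).

    Idempotent up to floating tolerance: a normalized image has zero mean and
    unit variance, so normalizing again is (numerically) the identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if fov_mask is not None:
        sel = np.asarray(fov_mask).astype(bool)
        if not sel.any():
            raise ValueError("empty FOV mask")
        region = img[sel]
    else:
        region = img.reshape(-1, img.shape[-1]) if img.ndim == 3 else img.reshape(-1, 1)
    mean = region.reshape(-1, img.shape[-1] if img.ndim == 3 else 1).mean(axis=0)
    std = region.reshape(-1, img.shape[-1] if img.ndim == 3 else 1).std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    if img.ndim == 3:
        return (img - mean[None, None, :]) / std[None, None, :]
    return (img - mean[0]) / std[0]


def apply_geometry(arr: np.ndarray, record: GeometricRecord) -> np.ndarray:
    """Apply exactly the rotation and flips in ``record`` to an array.

    90-degree multiples use ``np.rot90`` (exact, any dtype); other angles use
    bilinear interpolation and are only appropriate for float images.
    """
    out = np.asarray(arr)
    if record.is_exact:
        k = int(round(float(record.angle_deg) / 90.0)) % 4
        if k:
            out = np.rot90(out, k=k, axes=(0, 1))
    else:
        out = ndimage.rotate(out.astype(np.float64), record.angle_deg, axes=(1, 0),
                             reshape=False, order=1, mode="constant")
    if record.flip_h:
        out = out[:, ::-1]
    if record.flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _sample_geometry(rng: np.random.Generator, cfg: AugmentConfig) -> GeometricRecord:
    if cfg.rotate:
        angle = float(rng.uniform(0, 360)) if cfg.arbitrary_rotation else float(
            90 * rng.integers(0, 4))
    else:
        angle = 0.0
    flip_h = bool(rng.random() < 0.5) if cfg.flip else False
    flip_v = bool(rng.random() < 0.5) if cfg.flip else False
    return GeometricRecord(angle_deg=angle, flip_h=flip_h, flip_v=flip_v)


def _sample_photometry(rng: np.random.Generator, cfg: AugmentConfig) -> PhotometricRecord:
    w = float(rng.uniform(0.0, cfg.gray_max))
    factors = tuple(float(f) for f in rng.uniform(1.0 - cfg.jitter, 1.0 + cfg.jitter, size=3))
    return PhotometricRecord(gray_weight=w, jitter=factors)


def apply_photometry(image: np.ndarray, record: PhotometricRecord) -> np.ndarray:
    gray = image.mean(axis=-1, keepdims=True)
    out = (1.0 - record.gray_weight) * image + record.gray_weight * gray
    return out * np.asarray(record.jitter, dtype=np.float64)[None, None, :]


def make_augmented_pair(
    image: np.ndarray,
    seed: int,
    config: AugmentConfig = AugmentConfig(),
    fov_mask: np.ndarray | None = None,
) -> AugmentedPair:
    """Build the weak/strong view pair of one target image.

    The weak view is geometry (rotation + flips) followed by intensity
    normalization over the (transformed) FOV; the strong view applies the
    *same* geometry, then gray-scale blending and color jitter on top of the
    normalized weak view.  Deterministic per (image, seed, config).
    """
    rng = np.random.default_rng(seed)
    geo = _sample_geometry(rng, config)
    photo = _sample_photometry(rng, config)

    img_t = apply_geometry(np.asarray(image, dtype=np.float64), geo)
    fov_t = apply_geometry(fov_mask, geo) if fov_mask is not None else None
    weak = normalize_intensity(img_t, fov_t)
    strong = apply_photometry(weak, photo)
    return AugmentedPair(weak_image=weak, strong_image=strong,
                         geometric_record=geo, photometric_record=photo)
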