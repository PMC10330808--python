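"""Dataset layout, PNG round-tripping, and overlay rendering.

Datasets live on disk the way public fundus sets are usually packaged::

    <root>/images/<stem>.png        8-bit RGB
    <root>/masks/<stem>.png         8-bit single channel, vessel = 255
    <root>/fov/<stem>.png           8-bit single channel, FOV disc = 255

Images and masks are paired by filename stem, ordered lexicographically so a
directory always loads the same way.  Masks binarize at >127 on load, which
lets real DRIVE/CHASEDB1/IOSTAR folders drop in unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .engine import Sample

_IMG_EXTS = (".png", ".tif", ".tiff")


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0,1] RGB array as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file to float64 RGB in [0,1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr.astype(np.float64) / 255.0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as {0,255} single-channel PNG."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask PNG, binarizing at >127."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def save_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Export a {0,1,2} label map for inspection: 0 -> 0, 1 -> 255, 2 -> 128."""
    lab = np.asarray(labels)
    if not np.isin(lab, (0, 1, 2)).all():
        raise ValueError("labels must be in {0, 1, 2}")
    enc = np.zeros(lab.shape, dtype=np.uint8)
    enc[lab == 1] = 255
    enc[lab == 2] = 128
    iio.imwrite(Path(path), enc)


def save_probability_png(path: str | Path, prob: np.ndarray) -> None:
    """Export a [0,1] probability map as an 8-bit grayscale PNG."""
    p = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (p * 255).round().astype(np.uint8))


@dataclass(frozen=True)
class ImageRecord:
    stem: str
    image_path: Path
    mask_path: Path | None
    fov_path: Path | None


@dataclass
class DatasetManifest:
    """Lexicographically ordered image/mask/FOV triples under one root."""

    root: Path
    records: list[ImageRecord]
    domain_id: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def load_sample(self, record: ImageRecord) -> Sample:
        return Sample(
            image=load_image(record.image_path),
            mask=load_mask(record.mask_path) if record.mask_path else None,
            fov=load_mask(record.fov_path) if record.fov_path else None,
        )

    def load_all(self) -> list[Sample]:
        return [self.load_sample(r) for r in self.records]


def load_dataset(root: str | Path, expect_masks: bool = True) -> DatasetManifest:
    """Scan an images/masks/fov directory tree into a manifest.

    Raises with the offending stems listed when ``expect_masks`` is set and
    some image has no mask (or a mask has no image).
    """
    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")

    def _stems(d: Path) -> dict[str, Path]:
        if not d.is_dir():
            return {}
        return {p.stem: p for p in sorted(d.iterdir()) if p.suffix.lower() in _IMG_EXTS}

    images = _stems(img_dir)
    masks = _stems(root / "masks")
    fovs = _stems(root / "fov")
    if expect_masks:
        missing = sorted(set(images) ^ set(masks))
        if missing:
            raise ValueError(f"unpaired image/mask stems under {root}: {missing}")
    records = [
        ImageRecord(stem=s, image_path=images[s], mask_path=masks.get(s),
                    fov_path=fovs.get(s))
        for s in sorted(images)
    ]
    if not records:
        raise ValueError(f"no images found under {root}")
    return DatasetManifest(root=root, records=records, domain_id=root.name)


def write_domain(root: str | Path, samples, stems=None) -> None:
    """Write Samples as an images/masks/fov tree."""
    root = Path(root)
    for sub in ("images", "masks", "fov"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = stems[i] if stems else f"{i:03d}"
        save_image(root / "images" / f"{stem}.png", s.image)
        if s.mask is not None:
            save_mask(root / "masks" / f"{stem}.png", s.mask)
        if s.fov is not None:
            save_mask(root / "fov" / f"{stem}.png", s.fov)


def write_manifest_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# fixed overlay palette: green = hit, red = spurious, blue = missed
_TP = np.array([0.1, 0.9, 0.1])
_FP = np.array([0.95, 0.15, 0.1])
_FN = np.array([0.15, 0.35, 0.95])


def render_overlay(
    image: np.ndarray, pred: np.ndarray, gt: np.ndarray | None = None
) -> np.ndarray:
    """Colour-code a prediction over a dimmed copy of the image.

    With ground truth: TP green, FP red, FN blue.  Without: the predicted
    vessel pixels are drawn in the TP colour.  Pure function.
    """
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    p = np.asarray(pred).astype(bool)
    if p.shape != img.shape[:2]:
        raise ValueError("prediction shape must match image")
    out = 0.5 * img.copy()
    if gt is None:
        contour = p & ~ndimage.binary_erosion(p)
        out[contour] = _TP
        return out
    g = np.asarray(gt).astype(bool)
    if g.shape != p.shape:
        raise ValueError("ground-truth shape must match prediction")
    out[p & g] = _TP
    out[p & ~g] = _FP
    out[~p & g] = _FN
    return out
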