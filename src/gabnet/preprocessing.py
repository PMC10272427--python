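"""Image loading, bilinear resizing and min-max normalisation.

Inputs are grayscale or RGB retinal OCT B-scans stored one directory
per class.  Preprocessing is deliberately minimal: resize to the network
input size with bilinear interpolation (half-pixel centres), then rescale
each image to [0, 1] with the global per-image min and max,

    X_norm = (X - X_min) / (X_max - X_min).

A constant image (X_max == X_min) maps to all zeros — the formula is
undefined there and zeros are inert downstream.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "load_image",
    "resize_bilinear",
    "minmax_normalize",
    "load_dataset",
    "prepare_image",
    "IMAGE_EXTENSIONS",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as a float array (H, W) or (H, W, 3)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if ("A" in im.mode or im.mode == "P") else "L")
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return arr


def resize_bilinear(img: np.ndarray, h: int, w: int, to_rgb: bool = False) -> np.ndarray:
    """Bilinear resize to exactly (h, w); half-pixel-centre convention.

    Channel count is preserved; with ``to_rgb`` a grayscale input is
    replicated to 3 channels (for models expecting RGB).
    """
    if h < 1 or w < 1:
        raise ValueError("target size must be at least 1x1")
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    out = _sk_resize(img, (h, w), order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    if to_rgb and out.ndim == 2:
        out = np.repeat(out[:, :, None], 3, axis=2)
    return out


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] with the global (all pixels, all channels) min/max."""
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def prepare_image(path, h: int, w: int, to_rgb: bool = False) -> np.ndarray:
    """Load -> resize -> normalize, returning (h, w, C) in [0, 1]."""
    out = minmax_normalize(resize_bilinear(load_image(path), h, w, to_rgb=to_rgb))
    if out.ndim == 2:
        out = out[:, :, None]
    return out


def load_dataset(root_dir, per_class_cap: int | None = None,
                 seed: int | None = None) -> tuple[list[tuple[Path, int]], list[str]]:
    """Enumerate a directory-per-class image tree.

    Returns ``(records, class_names)`` where records are (path, label)
    pairs.  Listing is deterministic: class folders and paths are sorted;
    when ``seed`` is given the records are shuffled with that seed
    (reproducibly).  ``per_class_cap`` keeps at most that many images per
    class — the "limited model" regime of training on a balanced subset.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"dataset root {root} contains no class directories")
    class_names = [p.name for p in class_dirs]
    records: list[tuple[Path, int]] = []
    for label, cdir in enumerate(class_dirs):
        paths = []
        for p in sorted(cdir.iterdir()):
            if not p.is_file():
                continue
            if p.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.info("skipping non-image file %s", p)
                continue
            paths.append(p)
        if not paths:
            warnings.warn(f"class directory {cdir} contains no images", stacklevel=2)
        if per_class_cap is not None:
            paths = paths[:per_class_cap]
        records.extend((p, label) for p in paths)
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
    return records, class_names
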