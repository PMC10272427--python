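"""Synthetic retinal-OCT B-scan generator with ground-truth lesion masks.

Real OCT B-scans show a stack of bright, gently curved retinal layer
bands over a dark vitreous/choroid background, corrupted by strong
multiplicative speckle.  The generator emulates exactly that structure —
four bright layer bands following a shared smooth displacement curve,
gamma speckle — and adds one class-specific lesion:

* ``CNV``     one bright irregular blob beneath / disrupting the bands
              (subretinal neovascular membrane);
* ``DME``     2-4 dark elliptical cysts inside the band stack
              (intraretinal fluid);
* ``DRUSEN``  4-8 small bright bumps deforming the lowest band
              (deposits on the retinal pigment epithelium);
* ``NORMAL``  the unmodified background.

Every sample carries a binary lesion mask (empty for NORMAL), so lesion
localisation by Grad-CAM can be scored quantitatively.  All geometry and
noise constants are declared fixture parameters of this package — they
make the classes learnable but not trivially separable at desk scale and
are not derived from any real dataset.  Class imbalance can mirror the
UCSD retinal-OCT proportions (37,206 / 11,349 / 8,617 / 51,140 for
CNV/DME/drusen/normal) via the ``ucsd_proportions`` preset.

Determinism: each sample uses its own RNG stream keyed by
``(global_seed, sample_index)``, so a dataset is reproducible under
partial regeneration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "CLASSES",
    "UCSD_COUNTS",
    "Background",
    "SyntheticSample",
    "DatasetSpec",
    "render_background",
    "render_class",
    "generate_sample",
    "generate_arrays",
    "generate_dataset",
]

CLASSES = ("CNV", "DME", "DRUSEN", "NORMAL")
UCSD_COUNTS = {"CNV": 37206, "DME": 11349, "DRUSEN": 8617, "NORMAL": 51140}

# fixture geometry bounds, as fractions of image area
MIN_LESION_AREA_FRAC = 0.0005
MAX_LESION_AREA_FRAC = 0.12
_MAX_RETRIES = 25


@dataclass
class Background:
    """A rendered lesion-free B-scan plus the band geometry needed to place lesions."""

    clean: np.ndarray          # noiseless float image, (S, S)
    image: np.ndarray          # speckled image in [0, 255], float
    band_center_rows: list[np.ndarray]  # per band: center row per column, (S,)
    band_thickness: list[float]
    band_brightness: list[float]
    base_level: float
    noise_level: float

    @property
    def size(self) -> int:
        return self.clean.shape[0]

    def band_stack_limits(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column top and bottom rows of the whole band stack."""
        tops = np.min(
            [c - t / 2 for c, t in zip(self.band_center_rows, self.band_thickness)], axis=0
        )
        bottoms = np.max(
            [c + t / 2 for c, t in zip(self.band_center_rows, self.band_thickness)], axis=0
        )
        return tops, bottoms


@dataclass
class SyntheticSample:
    image: np.ndarray          # uint8 (S, S)
    label: str
    label_index: int
    lesion_mask: np.ndarray    # bool (S, S), all False for NORMAL
    gen_params: dict
    seed: object = None


def _speckle(rng: np.random.Generator, img: np.ndarray, noise_level: float) -> np.ndarray:
    """Multiplicative gamma speckle with unit mean and sd = noise_level."""
    if noise_level <= 0:
        return np.clip(img, 0, 255)
    shape = 1.0 / noise_level**2
    mult = rng.gamma(shape, 1.0 / shape, size=img.shape)
    return np.clip(img * mult, 0, 255)


def render_background(rng: np.random.Generator, size: int = 128,
                      noise_level: float = 0.18) -> Background:
    """Dark background + four bright curved layer bands + speckle."""
    if size < 32:
        raise ValueError("image size below 32 px cannot hold the band geometry")
    s = size
    x = np.arange(s)
    base = rng.uniform(5.0, 15.0)
    clean = np.full((s, s), base)

    # shared smooth vertical displacement: sinusoid + tilt
    amp = rng.uniform(0.01, 0.03) * s
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    tilt = rng.uniform(-0.03, 0.03)
    curve = amp * np.sin(2 * np.pi * freq * x / s + phase) + tilt * (x - s / 2)

    n_bands = 4
    stack_top = rng.uniform(0.36, 0.40) * s
    yy = np.arange(s)[:, None]
    centers, thicknesses, brightnesses = [], [], []
    cursor = stack_top
    for _ in range(n_bands):
        thickness = rng.uniform(0.03, 0.045) * s
        gap = rng.uniform(0.02, 0.035) * s
        center = cursor + thickness / 2 + curve
        brightness = rng.uniform(170.0, 210.0)
        band = np.abs(yy - center[None, :]) <= thickness / 2
        clean[band] = brightness
        centers.append(center)
        thicknesses.append(thickness)
        brightnesses.append(brightness)
        cursor += thickness + gap

    image = _speckle(rng, clean, noise_level)
    return Background(
        clean=clean,
        image=image,
        band_center_rows=centers,
        band_thickness=thicknesses,
        band_brightness=brightnesses,
        base_level=base,
        noise_level=noise_level,
    )


def _ellipse_mask(size: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy = np.arange(size)[:, None]
    xx = np.arange(size)[None, :]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _draw_cnv(rng, bg: Background) -> tuple[np.ndarray, np.ndarray, dict]:
    """One bright irregular blob beneath the band stack: union of ellipses."""
    s = bg.size
    _, bottoms = bg.band_stack_limits()
    cx = rng.uniform(0.15 * s, 0.85 * s)
    col = int(np.clip(cx, 0, s - 1))
    cy = bottoms[col] + rng.uniform(0.0, 0.05 * s)
    brightness = rng.uniform(210.0, 250.0)
    mask = np.zeros((s, s), dtype=bool)
    n_lobes = int(rng.integers(3, 6))
    for _ in range(n_lobes):
        dx, dy = rng.uniform(-0.05 * s, 0.05 * s, size=2)
        rx = rng.uniform(0.05 * s, 0.11 * s)
        ry = rng.uniform(0.04 * s, 0.08 * s)
        mask |= _ellipse_mask(s, cx + dx, cy + dy, rx, ry)
    clean = bg.clean.copy()
    clean[mask] = brightness
    return clean, mask, {"kind": "cnv_blob", "cx": cx, "cy": float(cy),
                         "brightness": brightness, "lobes": n_lobes}


def _draw_dme(rng, bg: Background) -> tuple[np.ndarray, np.ndarray, dict]:
    """2-4 dark elliptical cysts inside the band stack."""
    s = bg.size
    tops, bottoms = bg.band_stack_limits()
    n_cysts = int(rng.integers(2, 5))
    mask = np.zeros((s, s), dtype=bool)
    clean = bg.clean.copy()
    darkness = rng.uniform(0.0, 6.0)
    placed = []
    for _ in range(n_cysts):
        for _ in range(_MAX_RETRIES):
            cx = rng.uniform(0.12 * s, 0.88 * s)
            col = int(np.clip(cx, 0, s - 1))
            rx = rng.uniform(0.04 * s, 0.10 * s)
            ry = rng.uniform(0.025 * s, 0.05 * s)
            lo, hi = tops[col] + ry, bottoms[col] - ry
            if hi - lo < 1.0:
                continue
            cy = rng.uniform(lo, hi)
            placed.append((cx, float(cy), rx, ry))
            m = _ellipse_mask(s, cx, cy, rx, ry)
            mask |= m
            break
    clean[mask] = darkness
    return clean, mask, {"kind": "dme_cysts", "cysts": placed, "darkness": darkness}


def _draw_drusen(rng, bg: Background) -> tuple[np.ndarray, np.ndarray, dict]:
    """4-8 small bright bumps deforming the lowest band."""
    s = bg.size
    lowest = int(np.argmax([c.mean() for c in bg.band_center_rows]))
    center = bg.band_center_rows[lowest]
    half = bg.band_thickness[lowest] / 2
    brightness = 255.0
    n_bumps = int(rng.integers(4, 9))
    mask = np.zeros((s, s), dtype=bool)
    clean = bg.clean.copy()
    bumps = []
    for _ in range(n_bumps):
        cx = rng.uniform(0.1 * s, 0.9 * s)
        col = int(np.clip(cx, 0, s - 1))
        rx = rng.uniform(0.025 * s, 0.06 * s)
        ry = rng.uniform(0.025 * s, 0.05 * s)
        cy = center[col] + half  # sits on the band's lower edge
        m = _ellipse_mask(s, cx, cy, rx, ry)
        mask |= m
        bumps.append((cx, float(cy), rx, ry))
    clean[mask] = brightness
    return clean, mask, {"kind": "drusen_bumps", "bumps": bumps, "brightness": brightness}


_LESION_PAINTERS = {"CNV": _draw_cnv, "DME": _draw_dme, "DRUSEN": _draw_drusen}


def render_class(rng: np.random.Generator, label: str, background: Background) -> SyntheticSample:
    """Add the class lesion to a background and apply fresh speckle.

    Lesion geometry is re-sampled (bounded retries) until the mask area
    lies within the configured fraction bounds and inside the image.
    """
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}, got {label!r}")
    s = background.size
    if label == "NORMAL":
        image = np.clip(background.image, 0, 255).astype(np.uint8)
        return SyntheticSample(
            image=image, label=label, label_index=CLASSES.index(label),
            lesion_mask=np.zeros((s, s), dtype=bool),
            gen_params={"kind": "normal", "noise_level": background.noise_level},
        )
    painter = _LESION_PAINTERS[label]
    lo, hi = MIN_LESION_AREA_FRAC * s * s, MAX_LESION_AREA_FRAC * s * s
    for _ in range(_MAX_RETRIES):
        clean, mask, params = painter(rng, background)
        if lo <= mask.sum() <= hi:
            image = _speckle(rng, clean, background.noise_level).astype(np.uint8)
            params["noise_level"] = background.noise_level
            return SyntheticSample(
                image=image, label=label, label_index=CLASSES.index(label),
                lesion_mask=mask, gen_params=params,
            )
    raise RuntimeError(
        f"could not place a {label} lesion within area bounds after {_MAX_RETRIES} tries"
    )


def generate_sample(label: str, global_seed: int, index: int, size: int = 128,
                    noise_level: float = 0.18) -> SyntheticSample:
    """One sample from the stream keyed by (global_seed, index)."""
    rng = np.random.default_rng([int(global_seed), int(index)])
    bg = render_background(rng, size=size, noise_level=noise_level)
    sample = render_class(rng, label, bg)
    sample.seed = (int(global_seed), int(index))
    return sample


@dataclass
class DatasetSpec:
    """What to generate: class counts, image size, noise, splits, seed.

    ``imbalance='balanced'`` gives ``n_per_class`` images per class;
    ``imbalance='ucsd_proportions'`` scales the UCSD class counts by
    ``scale`` (rounded).  Explicit ``counts`` override both.
    """

    n_per_class: int = 200
    counts: dict[str, int] | None = None
    imbalance: str = "balanced"
    scale: float = 0.01
    image_size: int = 128
    noise_level: float = 0.18
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.imbalance not in ("balanced", "ucsd_proportions"):
            raise ValueError("imbalance must be 'balanced' or 'ucsd_proportions'")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")

    def class_counts(self) -> dict[str, int]:
        if self.counts is not None:
            missing = set(CLASSES) - set(self.counts)
            if missing:
                raise ValueError(f"counts missing classes: {sorted(missing)}")
            if any(v < 0 for v in self.counts.values()):
                raise ValueError("counts must be nonnegative")
            return {c: int(self.counts[c]) for c in CLASSES}
        if self.imbalance == "ucsd_proportions":
            return {c: int(round(UCSD_COUNTS[c] * self.scale)) for c in CLASSES}
        return {c: int(self.n_per_class) for c in CLASSES}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "DatasetSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _assign_splits(rng: np.random.Generator, n: int, spec: DatasetSpec) -> list[str]:
    """Stratified split of n per-class samples into train/val/test."""
    n_test = int(round(spec.test_frac * n))
    n_val = int(round(spec.val_frac * n))
    labels = ["test"] * n_test + ["val"] * n_val + ["train"] * (n - n_test - n_val)
    order = rng.permutation(n)
    return [labels[i] for i in np.argsort(order)]


def generate_arrays(spec: DatasetSpec) -> dict:
    """Generate a dataset in memory.

    Returns a dict with uint8 ``images`` (N, S, S), integer ``labels``,
    boolean ``masks`` (N, S, S), string ``splits`` and ``class_names``.
    """
    counts = spec.class_counts()
    images, labels, masks, splits = [], [], [], []
    split_rng = np.random.default_rng([spec.seed, 2**20])
    index = 0
    for label in CLASSES:
        n = counts[label]
        class_splits = _assign_splits(split_rng, n, spec)
        for i in range(n):
            sample = generate_sample(label, spec.seed, index,
                                     size=spec.image_size, noise_level=spec.noise_level)
            images.append(sample.image)
            labels.append(sample.label_index)
            masks.append(sample.lesion_mask)
            splits.append(class_splits[i])
            index += 1
    return {
        "images": np.stack(images) if images else np.zeros((0, spec.image_size, spec.image_size), np.uint8),
        "labels": np.asarray(labels, dtype=np.int64),
        "masks": np.stack(masks) if masks else np.zeros((0, spec.image_size, spec.image_size), bool),
        "splits": np.asarray(splits),
        "class_names": list(CLASSES),
    }


def generate_dataset(spec: DatasetSpec, out_dir) -> Path:
    """Write PNG images (CLASS/ folders), masks and a manifest CSV.

    Returns the manifest path.  Regeneration with the same spec is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = spec.class_counts()
    split_rng = np.random.default_rng([spec.seed, 2**20])
    rows = []
    index = 0
    for label in CLASSES:
        (out / label).mkdir(exist_ok=True)
        n = counts[label]
        class_splits = _assign_splits(split_rng, n, spec)
        for i in range(n):
            sample = generate_sample(label, spec.seed, index,
                                     size=spec.image_size, noise_level=spec.noise_level)
            img_path = out / label / f"{label.lower()}_{index:06d}.png"
            Image.fromarray(sample.image).save(img_path)
            mask_path = ""
            if sample.lesion_mask.any():
                mdir = out / "masks" / label
                mdir.mkdir(parents=True, exist_ok=True)
                mask_path = mdir / f"{label.lower()}_{index:06d}.png"
                Image.fromarray(sample.lesion_mask.astype(np.uint8) * 255).save(mask_path)
            rows.append({
                "path": str(img_path.relative_to(out)),
                "label": label,
                "split": class_splits[i],
                "seed": f"{spec.seed}:{index}",
                "mask_path": str(mask_path.relative_to(out)) if mask_path else "",
            })
            index += 1
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "split", "seed", "mask_path"])
        writer.writeheader()
        writer.writerows(rows)
    spec.to_yaml(out / "spec.yaml")
    return manifest
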