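"""Grad-CAM heatmaps and lesion-localisation scoring.

For a target class c and a rank-3 activation A of a chosen layer, the
channel weights are the spatial means of d(score_c)/dA; the map is
ReLU(sum_k w_k A_k), bilinearly upsampled to the input size and min-max
normalised (an all-zero map stays zero).  The default layer is the last
global-attention-block output — the deepest feature map the classifier
re-weights before pooling.

With synthetic data the ground-truth lesion mask is known, so a heatmap
can be scored: :func:`localization_score` is the fraction of the top
10% heatmap pixels that fall inside the mask.  Under a random heatmap
its expectation equals the mask's area fraction, which gives a chance
level to test against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .model import GABNet
from .nn import Module, Tensor
from .preprocessing import resize_bilinear

__all__ = ["Heatmap", "gradcam", "localization_score", "overlay"]


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1] at input resolution
    class_index: int
    layer_name: str


def gradcam(model: GABNet, image: np.ndarray, class_index: int | None = None,
            layer_name: str | None = None) -> Heatmap:
    """Grad-CAM heatmap of one preprocessed image (H, W, C) in [0, 1].

    ``class_index`` defaults to the predicted class; ``layer_name``
    defaults to the last attention-block output (or the last block for a
    model built without attention).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if layer_name is None:
        gabs = model.gab_layer_names
        layer_name = gabs[-1] if gabs else model.layer_names[-1]
    elif layer_name not in model.layer_names:
        raise ValueError(
            f"layer {layer_name!r} not found; eligible layers: {model.layer_names}"
        )
    was_training = model.training
    model.eval()
    try:
        x = Tensor(image[None], requires_grad=True)
        logits = model.forward(x, record=True)
        act = model.activations[layer_name]
        if act.ndim != 4:
            raise ValueError(f"layer {layer_name!r} does not produce a rank-3 feature map")
        if class_index is None:
            class_index = int(np.argmax(logits.data[0]))
        elif not 0 <= class_index < logits.data.shape[1]:
            raise ValueError(f"class_index {class_index} out of range")
        model.zero_grad()
        seed = np.zeros_like(logits.data)
        seed[0, class_index] = 1.0
        logits.backward(seed)
        grads = act.grad[0]          # (h, w, c)
        weights = grads.mean(axis=(0, 1))
        cam = np.maximum((act.data[0] * weights).sum(axis=2), 0.0)
    finally:
        model.train(was_training)
    cam = resize_bilinear(cam, image.shape[0], image.shape[1])
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, class_index=class_index, layer_name=layer_name)


def localization_score(heatmap: Heatmap | np.ndarray, lesion_mask: np.ndarray,
                       top_fraction: float = 0.1) -> float:
    """Fraction of the top-`top_fraction` heatmap pixels inside the mask."""
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    mask = np.asarray(lesion_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError(f"heatmap {values.shape} and mask {mask.shape} shapes differ")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if not mask.any():
        return 0.0
    n = values.size
    k = max(1, int(np.ceil(top_fraction * n)))
    flat = values.reshape(-1)
    top_idx = np.argpartition(flat, n - k)[n - k:]
    return float(mask.reshape(-1)[top_idx].mean())


def overlay(heatmap: Heatmap | np.ndarray, image: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto a grayscale image (uint8 RGB)."""
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape != values.shape:
        raise ValueError("image and heatmap shapes differ")
    colored = colormaps[cmap](values)[:, :, :3]
    gray = np.repeat(img[:, :, None], 3, axis=2)
    blend = (1 - alpha) * gray + alpha * colored
    return np.clip(blend * 255, 0, 255).astype(np.uint8)
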