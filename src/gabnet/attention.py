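"""Global attention block: height, width and channel attention for feature maps.

A convolutional feature map ``T`` of shape (m, n, k) — height, width,
channels — is re-weighted along all three axes:

* the *height branch* pools T over the height axis (average and max),
  concatenates the two (1, n, k) maps along the channel axis, and passes
  them through a bottleneck of two pointwise convolutions ``d`` (2k ->
  ceil(k/r)) and ``f`` (ceil(k/r) -> k), each fused with batch norm and
  ReLU, yielding a (1, n, k) weight map;
* the *width branch* mirrors this along the width axis, giving (m, 1, k),
  sharing ``d``/``f`` with the height branch;
* the *channel branch* applies a shared two-layer MLP (``W0``: dense k ->
  ceil(k/r) with ReLU; ``W1``: dense ceil(k/r) -> k with sigmoid) to the
  global average- and max-pooled channel descriptors and sums the two
  sigmoid outputs, giving a (1, 1, k) map with entries in (0, 2);
* the output is the elementwise broadcast product
  ``O = T * H * W * C``.

By default the spatial branches end in a sigmoid so their weights lie in
(0, 1); set ``terminal_sigmoid=False`` for the literal ReLU-terminated
form.  The block is plug-and-play: output shape always equals input
shape, so it can be inserted after any convolutional layer.

Two API levels are provided: :class:`GlobalAttentionBlock` is a batched
NHWC module for use inside networks; the functional helpers
(:func:`pool_height`, :func:`height_attention`, :func:`gab_apply`, ...)
operate on single (m, n, k) arrays and are the reference surface for
testing and exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import (
    ACTIVATIONS,
    BatchNorm,
    Dense,
    Module,
    Parameter,
    PointwiseConv,
    Sequential,
    Tensor,
    concat,
)

__all__ = [
    "GabParams",
    "AttentionMaps",
    "GlobalAttentionBlock",
    "pool_height",
    "pool_width",
    "pool_channel_global",
    "height_attention",
    "width_attention",
    "channel_attention",
    "gab_apply",
    "gab_param_count",
]


def _check_feature_map(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    if t.ndim != 3:
        raise ValueError(f"feature map must be rank-3 (height, width, channels), got shape {t.shape}")
    if 0 in t.shape:
        raise ValueError(f"feature map has an empty axis: shape {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValueError("feature map contains non-finite entries")
    return t


# ----------------------------------------------------------------- pooling ops
def pool_height(t: np.ndarray, mode: str = "avg") -> np.ndarray:
    """Pool over the height axis: (m, n, k) -> (1, n, k)."""
    t = _check_feature_map(t)
    if mode == "avg":
        return t.mean(axis=0, keepdims=True)
    if mode == "max":
        return t.max(axis=0, keepdims=True)
    raise ValueError(f"mode must be 'avg' or 'max', got {mode!r}")


def pool_width(t: np.ndarray, mode: str = "avg") -> np.ndarray:
    """Pool over the width axis: (m, n, k) -> (m, 1, k)."""
    t = _check_feature_map(t)
    if mode == "avg":
        return t.mean(axis=1, keepdims=True)
    if mode == "max":
        return t.max(axis=1, keepdims=True)
    raise ValueError(f"mode must be 'avg' or 'max', got {mode!r}")


def pool_channel_global(t: np.ndarray, mode: str = "avg") -> np.ndarray:
    """Global spatial pooling per channel: (m, n, k) -> (1, 1, k)."""
    t = _check_feature_map(t)
    if mode == "avg":
        return t.mean(axis=(0, 1), keepdims=True)
    if mode == "max":
        return t.max(axis=(0, 1), keepdims=True)
    raise ValueError(f"mode must be 'avg' or 'max', got {mode!r}")


# ------------------------------------------------------------------ the block
@dataclass
class GabParams:
    """Configuration of one global attention block.

    reduction_ratio
        Bottleneck ratio r; the reduced width is ceil(k / r).
    terminal_sigmoid
        Apply a sigmoid at the end of the height/width branches so their
        weights lie in (0, 1).  Off = literal ReLU-terminated branches.
    cbam_style_channel
        If True, sum the two MLP outputs *before* the sigmoid (range
        (0, 1), the convention of channel-attention blocks); if False,
        apply the sigmoid per path and sum (range (0, 2)).
    activation
        Activation inside the d/f transforms: 'relu' (default) or 'hswish'.
    """

    reduction_ratio: int = 8
    terminal_sigmoid: bool = True
    cbam_style_channel: bool = False
    activation: str = "relu"

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(ACTIVATIONS)}")


@dataclass
class AttentionMaps:
    """The three branch weight maps and the re-weighted output."""

    height_map: np.ndarray  # (1, n, k)
    width_map: np.ndarray  # (m, 1, k)
    channel_map: np.ndarray  # (1, 1, k)
    output: np.ndarray  # (m, n, k)


class GlobalAttentionBlock(Module):
    """Batched (B, H, W, C) global attention block.

    The d/f bottleneck is shared between the height and width branches
    (the transforms are pointwise, hence shape-agnostic over the spatial
    axes), and the W0/W1 MLP is shared between the average- and
    max-pooled channel descriptors.
    """

    def __init__(self, channels: int, params: GabParams | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = int(channels)
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        self.params = params or GabParams()
        rng = rng or np.random.default_rng()
        reduced = math.ceil(self.channels / self.params.reduction_ratio)
        self.reduced = reduced
        # d: 2k -> k/r, f: k/r -> k; pointwise conv + BN + activation
        # (the default ReLU is fused into the batch-norm node)
        if self.params.activation == "relu":
            self.d = Sequential(PointwiseConv(2 * self.channels, reduced, rng=rng),
                                BatchNorm(reduced, fuse_relu=True))
            self.f = Sequential(PointwiseConv(reduced, self.channels, rng=rng),
                                BatchNorm(self.channels, fuse_relu=True))
        else:
            act = ACTIVATIONS[self.params.activation]
            self.d = Sequential(PointwiseConv(2 * self.channels, reduced, rng=rng),
                                BatchNorm(reduced), act())
            self.f = Sequential(PointwiseConv(reduced, self.channels, rng=rng),
                                BatchNorm(self.channels), act())
        # shared channel MLP
        self.w0 = Dense(self.channels, reduced, rng=rng)
        self.w1 = Dense(reduced, self.channels, rng=rng)

    # ------------------------------------------------------------- branches
    def _spatial_branch(self, x: Tensor, axis: int) -> Tensor:
        """Pooled-concat-d-f branch along `axis` (1 = height, 2 = width)."""
        avg = x.mean(axis=axis, keepdims=True)
        mx = x.max(axis=axis, keepdims=True)
        y = concat([avg, mx], axis=3)
        y = self.f(self.d(y))
        # The outer average pooling over the branch axis is the identity:
        # that axis already has extent 1 after the inner pooling.
        if self.params.terminal_sigmoid:
            y = y.sigmoid()
        return y

    def height_branch(self, x: Tensor) -> Tensor:
        """(B, H, W, C) -> (B, 1, W, C)."""
        return self._spatial_branch(x, axis=1)

    def width_branch(self, x: Tensor) -> Tensor:
        """(B, H, W, C) -> (B, H, 1, C)."""
        return self._spatial_branch(x, axis=2)

    def channel_branch(self, x: Tensor) -> Tensor:
        """(B, H, W, C) -> (B, 1, 1, C)."""
        gap = x.mean(axis=(1, 2), keepdims=True)
        gmp = x.max(axis=(1, 2), keepdims=True)
        a = self.w1(self.w0(gap).relu())
        b = self.w1(self.w0(gmp).relu())
        if self.params.cbam_style_channel:
            return (a + b).sigmoid()
        return a.sigmoid() + b.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("GlobalAttentionBlock expects a (B, H, W, C) tensor")
        if x.shape[3] != self.channels:
            raise ValueError(
                f"block configured for {self.channels} channels, input has {x.shape[3]}"
            )
        h = self.height_branch(x)
        w = self.width_branch(x)
        c = self.channel_branch(x)
        return x * h * w * c


# ------------------------------------------------------- functional interface
def _as_batch(t: np.ndarray, block: GlobalAttentionBlock) -> Tensor:
    t = _check_feature_map(t)
    if t.shape[2] != block.channels:
        raise ValueError(
            f"block configured for {block.channels} channels, feature map has {t.shape[2]}"
        )
    return Tensor(t[None])


def height_attention(t: np.ndarray, block: GlobalAttentionBlock) -> np.ndarray:
    """Height-branch weights of a single (m, n, k) feature map: (1, n, k)."""
    return block.height_branch(_as_batch(t, block)).data[0]


def width_attention(t: np.ndarray, block: GlobalAttentionBlock) -> np.ndarray:
    """Width-branch weights of a single (m, n, k) feature map: (m, 1, k)."""
    return block.width_branch(_as_batch(t, block)).data[0]


def channel_attention(t: np.ndarray, block: GlobalAttentionBlock) -> np.ndarray:
    """Channel-branch weights of a single (m, n, k) feature map: (1, 1, k)."""
    return block.channel_branch(_as_batch(t, block)).data[0]


def gab_apply(t: np.ndarray, block: GlobalAttentionBlock) -> AttentionMaps:
    """Compute all three attention maps and the re-weighted output."""
    x = _as_batch(t, block)
    h = block.height_branch(x).data[0]
    w = block.width_branch(x).data[0]
    c = block.channel_branch(x).data[0]
    return AttentionMaps(height_map=h, width_map=w, channel_map=c,
                         output=np.asarray(t, dtype=np.float64) * h * w * c)


def gab_param_count(k: int, r: int = 8) -> int:
    """Closed-form trainable-parameter count of one block at k channels.

    d: pointwise 2k->kr plus batch norm (2 kr); f: pointwise kr->k plus
    batch norm (2 k); W0: dense k->kr with bias; W1: dense kr->k with
    bias, where kr = ceil(k/r).  Pointwise convolutions are bias-free
    (batch norm follows them); running moments are not trainable.
    """
    if k < 1 or r < 1:
        raise ValueError("k and r must be positive integers")
    kr = math.ceil(k / r)
    d = 2 * k * kr + 2 * kr
    f = kr * k + 2 * k
    w0 = k * kr + kr
    w1 = kr * k + k
    return d + f + w0 + w1
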