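"""GABNet: a lightweight depthwise-separable residual classifier.

The network is assembled from four kinds of parts:

* a *DSC module* — depthwise 3x3 convolution -> BN -> ReLU -> pointwise
  1x1 convolution -> BN -> ReLU (the factorised replacement for a full
  convolution);
* *DSCR Block A* — a downsampling residual block: two stacked DSC units
  followed by a 2x2 max-pool on the main path, and a pointwise
  projection plus max-pool on the shortcut, added elementwise;
* *DSCR Block B* — an identity-shortcut residual block of two DSC units
  at stride 1;
* a *global attention block* after each residual block (height, width
  and channel re-weighting; see :mod:`gabnet.attention`).

A global average pool and a single dense softmax head finish the model.
Architecture hyper-parameters (stage widths, depths, input size) are not
prescribed beyond "lightweight"; the defaults below target the
single-digit-million parameter regime, and a ``tiny`` preset keeps CPU
experiments fast.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .attention import GabParams, GlobalAttentionBlock, gab_param_count
from .nn import (
    BatchNorm,
    Dense,
    DepthwiseConv3x3,
    GlobalAvgPool,
    MaxPool2x2,
    Module,
    PointwiseConv,
    Sequential,
    Tensor,
    softmax,
)

__all__ = [
    "ArchitectureConfig",
    "DscModule",
    "DscrBlockA",
    "DscrBlockB",
    "GABNet",
    "build_dsc_module",
    "build_dscr_block_a",
    "build_dscr_block_b",
    "build_gabnet",
    "attach_gab",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureConfig:
    """Network-level hyper-parameters.

    ``input_size`` is (height, width, channels); each stage starts with a
    downsampling Block A at the stage width followed by
    ``blocks_per_stage - 1`` identity Block Bs; a GAB follows every
    residual block when ``use_gab`` is on (``gab_per_stage_only`` keeps
    only the one after the last block of each stage).
    """

    input_size: tuple[int, int, int] = (299, 299, 3)
    stem_filters: int = 32
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (2, 2, 3, 2)
    num_classes: int = 4
    use_gab: bool = True
    gab_per_stage_only: bool = False
    gab: GabParams = field(default_factory=GabParams)
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_widths) != len(self.blocks_per_stage):
            raise ValueError("stage_widths and blocks_per_stage must have equal length")
        if any(w < 1 for w in self.stage_widths) or any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("stage widths and depths must be positive")
        if isinstance(self.gab, dict):
            self.gab = GabParams(**self.gab)
        self.input_size = tuple(self.input_size)
        self.stage_widths = tuple(self.stage_widths)
        self.blocks_per_stage = tuple(self.blocks_per_stage)

    @classmethod
    def preset(cls, name: str, **overrides) -> "ArchitectureConfig":
        """Named presets: ``full`` (299x299 RGB) and ``tiny`` (128x128 grayscale)."""
        presets = {
            "full": dict(),
            "tiny": dict(
                input_size=(128, 128, 1),
                stem_filters=8,
                stage_widths=(16, 32, 64),
                blocks_per_stage=(1, 1, 1),
            ),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kwargs = presets[name] | overrides
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class DscModule(Module):
    """Depthwise 3x3 -> BN -> ReLU -> pointwise 1x1 -> BN -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng()
        self.depthwise = DepthwiseConv3x3(in_channels, stride=stride, rng=rng)
        self.bn1 = BatchNorm(in_channels, fuse_relu=True)
        self.pointwise = PointwiseConv(in_channels, out_channels, rng=rng)
        self.bn2 = BatchNorm(out_channels, fuse_relu=True)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.depthwise(x))
        x = self.bn2(self.pointwise(x))
        return x


class DscrBlockA(Module):
    """Downsampling residual block: DSC x2 + max-pool, projected shortcut."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dsc1 = DscModule(in_channels, out_channels, stride=1, rng=rng)
        self.dsc2 = DscModule(out_channels, out_channels, stride=1, rng=rng)
        self.pool_main = MaxPool2x2()
        self.shortcut_conv = PointwiseConv(in_channels, out_channels, rng=rng)
        self.shortcut_bn = BatchNorm(out_channels)
        self.pool_short = MaxPool2x2()

    def forward(self, x: Tensor) -> Tensor:
        main = self.pool_main(self.dsc2(self.dsc1(x)))
        short = self.pool_short(self.shortcut_bn(self.shortcut_conv(x)))
        assert main.shape == short.shape, (
            f"residual paths disagree: {main.shape} vs {short.shape}"
        )
        return main + short


class DscrBlockB(Module):
    """Identity-shortcut residual block: two DSC units at stride 1."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dsc1 = DscModule(channels, channels, stride=1, rng=rng)
        self.dsc2 = DscModule(channels, channels, stride=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.dsc2(self.dsc1(x)) + x


def build_dsc_module(in_channels: int, out_channels: int, stride: int = 1,
                     rng: np.random.Generator | None = None) -> DscModule:
    return DscModule(in_channels, out_channels, stride=stride, rng=rng)


def build_dscr_block_a(in_channels: int, out_channels: int,
                       rng: np.random.Generator | None = None) -> DscrBlockA:
    return DscrBlockA(in_channels, out_channels, rng=rng)


def build_dscr_block_b(channels: int, rng: np.random.Generator | None = None) -> DscrBlockB:
    return DscrBlockB(channels, rng=rng)


class GABNet(Module):
    """The assembled classifier.

    ``forward`` returns logits; :meth:`predict_proba` returns softmax
    probabilities.  When called with ``record=True`` the forward pass
    stores every named intermediate activation in ``self.activations``
    (used by Grad-CAM).
    """

    def __init__(self, cfg: ArchitectureConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w, c = cfg.input_size

        self.stem = DscModule(c, cfg.stem_filters, stride=2, rng=rng)
        h, w = math.ceil(h / 2), math.ceil(w / 2)

        self._layer_sequence: list[tuple[str, Module]] = [("stem", self.stem)]
        self.blocks: list[Module] = []
        self._block_names: list[str] = []
        in_ch = cfg.stem_filters
        for s, (width, depth) in enumerate(zip(cfg.stage_widths, cfg.blocks_per_stage), 1):
            if h < 2 or w < 2:
                raise ValueError(
                    f"stage {s} cannot downsample a {h}x{w} feature map "
                    f"(input {cfg.input_size[:2]} is too small for {s} downsampling stages)"
                )
            h, w = math.ceil(h / 2), math.ceil(w / 2)
            for b in range(1, depth + 1):
                if b == 1:
                    block: Module = DscrBlockA(in_ch, width, rng=rng)
                else:
                    block = DscrBlockB(width, rng=rng)
                name = f"stage{s}_block{b}"
                self.blocks.append(block)
                self._block_names.append(name)
                self._layer_sequence.append((name, block))
                if cfg.use_gab and (not cfg.gab_per_stage_only or b == depth):
                    gab = GlobalAttentionBlock(width, cfg.gab, rng=rng)
                    gname = f"stage{s}_block{b}_gab"
                    self.blocks.append(gab)
                    self._block_names.append(gname)
                    self._layer_sequence.append((gname, gab))
                in_ch = width
        self.final_spatial = (h, w)
        self.gap = GlobalAvgPool()
        self.head = Dense(in_ch, cfg.num_classes, rng=rng)
        self.activations: dict[str, Tensor] = {}

    # ---------------------------------------------------------------- naming
    @property
    def layer_names(self) -> list[str]:
        return [name for name, _ in self._layer_sequence]

    @property
    def gab_layer_names(self) -> list[str]:
        return [n for n in self.layer_names if n.endswith("_gab")]

    @property
    def parameter_count(self) -> int:
        return self.num_parameters()

    # --------------------------------------------------------------- forward
    def forward(self, x: Tensor, record: bool = False) -> Tensor:
        if record:
            self.activations = {}
        for name, layer in self._layer_sequence:
            x = layer(x)
            if record:
                self.activations[name] = x
        x = self.gap(x)
        return self.head(x)

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax class probabilities for an (N, H, W, C) image array."""
        images = np.asarray(images, dtype=np.float64)
        was_training = self.training
        self.eval()
        out = []
        for lo in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[lo : lo + batch_size]))
            out.append(softmax(logits.data))
        self.train(was_training)
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(images, batch_size=batch_size).argmax(axis=1)

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        """Plain-text layer table with parameter totals."""
        lines = [f"{'layer':<28}{'type':<24}{'params':>10}"]
        lines.append("-" * 62)
        for name, layer in self._layer_sequence:
            lines.append(f"{name:<28}{type(layer).__name__:<24}{layer.num_parameters():>10}")
        lines.append(f"{'head':<28}{'Dense':<24}{self.head.num_parameters():>10}")
        lines.append("-" * 62)
        total = self.parameter_count
        lines.append(f"total trainable parameters: {total} ({total / 1e6:.3f} M)")
        return "\n".join(lines)


def build_gabnet(cfg: ArchitectureConfig | None = None, **overrides) -> GABNet:
    """Build a GABNet from a config (or the default full-size config)."""
    if cfg is None:
        cfg = ArchitectureConfig(**overrides)
    elif overrides:
        cfg = ArchitectureConfig(**(cfg.to_dict() | overrides))
    return GABNet(cfg)


class _GabWrapped(Module):
    """A backbone with a global attention block appended to its feature map."""

    def __init__(self, backbone: Module, channels: int, params: GabParams | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.backbone = backbone
        self.gab = GlobalAttentionBlock(channels, params, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.gab(self.backbone(x))


def attach_gab(backbone: Module, channels: int, params: GabParams | None = None,
               rng: np.random.Generator | None = None) -> _GabWrapped:
    """Wrap any module producing (B, H, W, C) feature maps with a GAB.

    The block preserves the feature-map shape, so the wrapped model is a
    drop-in replacement for the backbone.
    """
    if not isinstance(channels, int) or channels < 1:
        raise ValueError("channels must be a known positive channel count")
    return _GabWrapped(backbone, channels, params, rng=rng)


def count_parameters(model: Module) -> int:
    """Total trainable scalar count of a model."""
    return model.num_parameters()


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: GABNet, path, extra: dict | None = None) -> None:
    """Save weights + architecture config as a single .npz archive."""
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    arrays = model.state_dict()
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> GABNet:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = ArchitectureConfig(**meta["config"])
    model = GABNet(cfg)
    model.load_state_dict(state)
    return model
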