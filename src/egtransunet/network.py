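"""Full segmentation network: residual encoder, attention-enhanced
bottleneck and skips, U-shaped decoder.

Layout (spatial sizes for an ``H x W`` input):

* **Encoder** — four stages of two residual blocks each, the first block
  of every stage downsampling by 2 (stage ``s`` output: ``H/2^s``),
  channel plan ``base_width * (1, 2, 4, 8)``.
* **PEM** refines encoder stage 3's output before it feeds both stage 4
  and its skip connection.
* **CSA** enhances the deepest (stage 4) feature at ``H/16``.
* **Decoder** — four stages of two convolutions + one bilinear
  upsampling.  Stage 1 refines the bottleneck (no skip); stages 2/3/4
  fuse skips from encoder stages 3/2/1 by concatenation, stage 2 through
  **SGA** when enabled.  Output spatial sizes double per stage:
  ``H/8, H/4, H/2, H``.
* **Head** — 1x1 convolution + sigmoid -> a ``1 x H x W`` probability map.

Every enhancement (PEM, CSA, SGA) has an ablation switch; with all three
off the model is the plain residual U-Net baseline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .attention import ConfigurationError
from .csa import CSA
from .nn import Module, Tensor, as_tensor
from .pem import PEM
from .sga import SGA

__all__ = [
    "ModelConfig",
    "ComplexityReport",
    "EGTransUNet",
    "build_model",
    "complexity",
    "dump_feature_maps",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters and ablation switches."""

    in_channels: int = 3
    base_width: int = 16
    n_heads: int = 4
    input_size: Tuple[int, int] = (320, 320)
    use_pem: bool = True
    use_csa: bool = True
    use_sga: bool = True
    dsa_residual: bool = False
    attention_axis: str = "key"  # or "printed"

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ConfigurationError(
                f"input_size must be divisible by 16 (four 2x downsamplings), got {h}x{w}"
            )
        if self.base_width < 1:
            raise ConfigurationError("base_width must be >= 1")
        if self.attention_axis not in ("key", "printed"):
            raise ConfigurationError(f"unknown attention_axis {self.attention_axis!r}")
        bottleneck_tokens = (h // 16) * (w // 16)
        if self.use_csa and bottleneck_tokens % self.n_heads:
            raise ConfigurationError(
                f"n_heads={self.n_heads} must divide the {bottleneck_tokens} bottleneck tokens"
            )
        for c in self.stage_channels:
            if c % self.n_heads:
                raise ConfigurationError(
                    f"n_heads={self.n_heads} must divide stage width {c}"
                )

    @property
    def stage_channels(self) -> Tuple[int, int, int, int]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class ComplexityReport:
    parameter_count: int
    mac_count: int


class ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN with an identity (or projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.bn_sc = nn.BatchNorm2d(c_out)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = self.bn_sc(self.shortcut(x)) if self.shortcut is not None else x
        return (out + skip).relu()


class EncoderStage(Module):
    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        self.block1 = ResidualBlock(c_in, c_out, stride=2, rng=rng)
        self.block2 = ResidualBlock(c_out, c_out, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class DecoderStage(Module):
    """Two convolutions then one bilinear 2x upsampling."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.up = nn.UpsampleBilinear2d(2)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return self.up(x)


class EGTransUNet(Module):
    """The assembled network.  See the module docstring for the wiring."""

    def __init__(self, config: ModelConfig, seed: Optional[int] = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        c1, c2, c3, c4 = config.stage_channels
        h, w = config.input_size

        self.enc1 = EncoderStage(config.in_channels, c1, rng=rng)
        self.enc2 = EncoderStage(c1, c2, rng=rng)
        self.enc3 = EncoderStage(c2, c3, rng=rng)
        self.enc4 = EncoderStage(c3, c4, rng=rng)

        self.pem = (
            PEM(c3, attention_axis=config.attention_axis,
                dsa_residual=config.dsa_residual, rng=rng)
            if config.use_pem else None
        )
        self.csa = (
            CSA(c4, (h // 16, w // 16), n_heads=config.n_heads, rng=rng)
            if config.use_csa else None
        )
        self.sga = SGA(c3, c3, n_heads=config.n_heads, rng=rng) if config.use_sga else None

        self.dec1 = DecoderStage(c4, c3, rng=rng)            # H/16 -> H/8
        self.dec2 = DecoderStage(2 * c3, c2, rng=rng)        # fuse enc3 skip
        self.dec3 = DecoderStage(2 * c2, c1, rng=rng)        # fuse enc2 skip
        self.dec4 = DecoderStage(2 * c1, c1, rng=rng)        # fuse enc1 skip
        self.head = nn.Conv2d(c1, 1, 1, rng=rng)

    def forward(self, x, record: Optional[dict] = None) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        h, w = self.config.input_size
        if x.shape[-2:] != (h, w):
            raise ValueError(
                f"expected {h}x{w} input (model was built for it), got "
                f"{x.shape[-2]}x{x.shape[-1]}; resize first"
            )

        def snap(name, t):
            if record is not None:
                record[name] = t.data.copy()

        e1 = self.enc1(x); snap("enc1", e1)
        e2 = self.enc2(e1); snap("enc2", e2)
        e3 = self.enc3(e2); snap("enc3", e3)
        if self.pem is not None:
            snap("pem_in", e3)
            e3 = self.pem(e3)
            snap("pem_out", e3)
        e4 = self.enc4(e3); snap("enc4", e4)
        z = self.csa(e4) if self.csa is not None else e4
        snap("csa", z)

        d1 = self.dec1(z); snap("dec1", d1)
        if self.sga is not None:
            fused = self.sga(low=e3, high=d1)
            snap("sga", fused)
        else:
            fused = nn.concat([e3, d1], axis=1)
        d2 = self.dec2(fused); snap("dec2", d2)
        d3 = self.dec3(nn.concat([e2, d2], axis=1)); snap("dec3", d3)
        d4 = self.dec4(nn.concat([e1, d3], axis=1)); snap("dec4", d4)
        out = self.head(d4).sigmoid()
        snap("output", out)
        return out


def build_model(config: ModelConfig, seed: Optional[int] = 0) -> EGTransUNet:
    """Construct a seeded model from a configuration."""
    return EGTransUNet(config, seed=seed)


def complexity(config: ModelConfig) -> ComplexityReport:
    """Exact parameter count and multiply–accumulate count at input_size.

    MACs are measured by instrumenting a real forward pass of a
    single-image batch, so added modules are reflected exactly.
    """
    model = build_model(config, seed=0).eval()
    h, w = config.input_size
    x = Tensor(np.zeros((1, config.in_channels, h, w)))
    with nn.count_macs() as macs:
        model(x)
    return ComplexityReport(parameter_count=model.n_parameters(), mac_count=macs[0])


_STAGES = (
    "enc1", "enc2", "enc3", "enc4", "pem_in", "pem_out", "csa",
    "dec1", "dec2", "dec3", "dec4", "sga", "output",
)


def dump_feature_maps(
    model: EGTransUNet, image, stage_names: Sequence[str]
) -> Dict[str, np.ndarray]:
    """Run one image through the model and return named intermediate maps.

    Each snapshot is a ``(C, H, W)`` array.  Unknown stage names raise
    ``KeyError``; names valid only for enabled modules (``pem_out``,
    ``csa``, ``sga``) raise ``KeyError`` when the module is disabled.
    """
    for name in stage_names:
        if name not in _STAGES:
            raise KeyError(f"unknown stage {name!r}; valid stages: {_STAGES}")
    record: dict = {}
    was_training = model.training
    model.eval()
    try:
        model(image, record=record)
    finally:
        model.train(was_training)
    out = {}
    for name in stage_names:
        if name not in record:
            raise KeyError(f"stage {name!r} is disabled in this configuration")
        arr = record[name]
        out[name] = arr[0] if arr.ndim == 4 else arr
    return out


def save_feature_grid(features: np.ndarray, path: str, max_channels: int = 16) -> None:
    """Write a grayscale grid of the first channels of a (C, H, W) map as PNG."""
    import imageio.v3 as iio

    c = min(features.shape[0], max_channels)
    cols = int(np.ceil(np.sqrt(c)))
    rows = int(np.ceil(c / cols))
    h, w = features.shape[1:]
    grid = np.zeros((rows * h, cols * w))
    for i in range(c):
        fmap = features[i]
        lo, hi = fmap.min(), fmap.max()
        norm = (fmap - lo) / (hi - lo) if hi > lo else np.zeros_like(fmap)
        r, col = divmod(i, cols)
        grid[r * h : (r + 1) * h, col * w : (col + 1) * w] = norm
    iio.imwrite(path, (grid * 255).astype(np.uint8))
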