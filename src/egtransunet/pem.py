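"""Progressive enhancement module (PEM).

Encoder-side refinement block: three parallel views of the same feature —
a plain 3x3 convolution and two dilated self-attention convolutions (DSA)
with dilation rates 2 and 3 — are cascaded through two gated convolutions
so that progressively larger receptive fields gate the extraction of the
original-scale feature.  The result is merged back onto the convolution
branch, so PEM is a drop-in, shape-preserving refiner.

The gated convolution (GC) computes ``ReLU(W_f . F_low) * sigmoid(W_g .
F_high)`` elementwise: the large-receptive-field stream ``F_high``
produces a (0,1) gate that modulates the embedded small-field stream.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import nn
from .attention import DilatedSelfAttention
from .nn import Module, Tensor, as_tensor


class GatedConv(Module):
    """Gate a feature embedding with a sigmoid map from a wider-field feature.

    Both projections are 1x1 convolutions mapping their input's channel
    count to a common ``out_channels``.
    """

    def __init__(
        self,
        high_channels: int,
        low_channels: int,
        out_channels: Optional[int] = None,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        out_channels = out_channels or low_channels
        self.conv_gate = nn.Conv2d(high_channels, out_channels, 1, bias=bias, rng=rng)
        self.conv_feat = nn.Conv2d(low_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, f_high, f_low) -> Tensor:
        f_high, f_low = as_tensor(f_high), as_tensor(f_low)
        if f_high.shape[-2:] != f_low.shape[-2:]:
            raise ValueError(
                f"gated_conv spatial mismatch: {f_high.shape[-2:]} vs {f_low.shape[-2:]}"
            )
        squeeze = f_high.ndim == 3
        if squeeze:
            f_high = f_high.reshape(1, *f_high.shape)
            f_low = f_low.reshape(1, *f_low.shape)
        gate = self.conv_gate(f_high).sigmoid()
        feat = self.conv_feat(f_low).relu()
        out = feat * gate
        return out.reshape(*out.shape[1:]) if squeeze else out


def gated_conv(f_high, f_low, gc: GatedConv) -> Tensor:
    """Functional form of :class:`GatedConv` given its parameters."""
    return gc(f_high, f_low)


class PEM(Module):
    """Cascaded multi-receptive-field enhancement with gated fusion.

    forward: ``A = conv3x3(x)``; ``B = DSA(x, dilation 2)``;
    ``C = DSA(x, dilation 3)``; ``g1 = GC(high=B, low=A)``;
    ``g2 = GC(high=C, low=g1)``; output ``= BN(A + g2) -> ReLU``.
    All branches keep the input channel count, so output shape equals
    input shape.
    """

    def __init__(
        self,
        channels: int,
        attention_axis: str = "key",
        dsa_residual: bool = False,
        pre_activation: bool = True,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.pre_activation = pre_activation
        self.conv_a = nn.Conv2d(channels, channels, 3, padding=1, bias=bias, rng=rng)
        self.bn_a = nn.BatchNorm2d(channels)
        self.dsa2 = DilatedSelfAttention(
            channels, 2, axis=attention_axis, residual=dsa_residual, bias=bias, rng=rng
        )
        self.dsa3 = DilatedSelfAttention(
            channels, 3, axis=attention_axis, residual=dsa_residual, bias=bias, rng=rng
        )
        self.gc1 = GatedConv(channels, channels, bias=bias, rng=rng)
        self.gc2 = GatedConv(channels, channels, bias=bias, rng=rng)
        self.bn_out = nn.BatchNorm2d(channels)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        a = self.conv_a(x)
        if self.pre_activation:
            a = self.bn_a(a).relu()
        b = self.dsa2(x)
        c = self.dsa3(x)
        g1 = self.gc1(f_high=b, f_low=a)
        g2 = self.gc2(f_high=c, f_low=g1)
        out = self.bn_out(a + g2).relu()
        return out.reshape(*out.shape[1:]) if squeeze else out
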