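"""Semantic guidance attention (SGA) on a skip connection.

The decoder (semantic, "high") stream queries the encoder (spatial,
"low") stream: both are projected to a common embedding width, channel
selection re-weights the key and query maps, and multi-head cross
attention aggregates the low-level values.  The attention context — the
refined low-level feature — is concatenated with the high-level feature
along channels, so the output has ``C_low + C_high`` channels.

Channel selection (CS) squeezes each channel to its spatial mean ``P``,
mixes the means through a learned ``c x c`` matrix, and gates channels
with ``A_w = sigmoid(W . P)``, each weight strictly in (0, 1).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import nn
from .attention import _attention_core
from .nn import Module, Parameter, Tensor, as_tensor


class ChannelSelection(Module):
    """Per-channel sigmoid gating from spatially pooled channel means."""

    def __init__(self, channels: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(channels), (channels, channels)))

    def forward(self, x, return_weights: bool = False):
        out, a_w = channel_selection(x, self.weight)
        return (out, a_w) if return_weights else out


def channel_selection(f, w) -> Tuple[Tensor, Tensor]:
    """Apply channel selection to a feature map.

    ``P_c`` = spatial mean of channel ``c``; ``A_w = sigmoid(w @ P)``;
    output ``= A_w * F`` per channel.  Returns ``(scaled_feature, A_w)``.
    Accepts ``(C, H, W)`` or ``(N, C, H, W)`` inputs.
    """
    f, w = as_tensor(f), as_tensor(w)
    squeeze = f.ndim == 3
    if squeeze:
        f = f.reshape(1, *f.shape)
    n, c, h, wd = f.shape
    if w.shape != (c, c):
        raise ValueError(f"channel-mixing matrix must be ({c}, {c}), got {w.shape}")
    p = f.mean(axis=(2, 3))                      # (N, C)
    a_w = nn.matmul(p, w.T).sigmoid()            # rows: sigmoid(W . P)
    out = f * a_w.reshape(n, c, 1, 1)
    if squeeze:
        out = out.reshape(c, h, wd)
        a_w = a_w.reshape(c)
    return out, a_w


class SGA(Module):
    """Cross-attention skip fusion: decoder queries attend over encoder keys.

    Output channel count is ``c_low + c_high`` (concatenation of the
    attention context with the high-level stream); any projection back to
    the decoder's planned width is left to the consumer.
    """

    def __init__(
        self,
        c_low: int,
        c_high: int,
        n_heads: int = 4,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_heads = n_heads
        self.c_low, self.c_high = c_low, c_high
        # common embedding width = c_low, so the context is a drop-in
        # replacement for the low-level feature
        self.proj_q = nn.Conv2d(c_high, c_low, 1, rng=rng)
        self.proj_k = nn.Conv2d(c_low, c_low, 1, rng=rng)
        self.proj_v = nn.Conv2d(c_low, c_low, 1, rng=rng)
        self.cs_k = ChannelSelection(c_low, rng=rng)
        self.cs_q = ChannelSelection(c_low, rng=rng)

    def forward(self, low, high, return_attention: bool = False):
        low, high = as_tensor(low), as_tensor(high)
        squeeze = low.ndim == 3
        if squeeze:
            low = low.reshape(1, *low.shape)
            high = high.reshape(1, *high.shape)
        if low.shape[-2:] != high.shape[-2:]:
            raise ValueError(
                f"SGA spatial mismatch: low {low.shape[-2:]} vs high {high.shape[-2:]}"
            )
        n, _, h, w = low.shape
        k = self.cs_k(self.proj_k(low))
        q = self.cs_q(self.proj_q(high))
        v = self.proj_v(low)
        to_tokens = lambda t: t.reshape(n, self.c_low, h * w).transpose(0, 2, 1)
        context, attn = _attention_core(
            to_tokens(q), to_tokens(k), to_tokens(v),
            bias=None, n_heads=self.n_heads, scale=None,
        )
        context = context.transpose(0, 2, 1).reshape(n, self.c_low, h, w)
        out = nn.concat([context, high], axis=1)
        if squeeze:
            out = out.reshape(*out.shape[1:])
            attn = attn.reshape(*attn.shape[1:])
        return (out, attn) if return_attention else out
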