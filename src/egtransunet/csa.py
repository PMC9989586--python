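"""Channel–spatial attention (CSA) at the network bottleneck.

Two multi-head self-attention stages run in series on the deepest encoder
feature:

1. **Channel MHSA** — each *channel* is a token whose embedding is the
   flattened spatial map (dimension ``h*w``).  No position bias is used.
2. **Spatial MHSA** — each *position* is a token whose embedding is the
   channel vector, with a trainable absolute position bias added to the
   attention logits.

Projections are per-token linear maps applied in the respective token
view (for spatial tokens this is exactly a 1x1 convolution across
channels; for channel tokens it is an ``h*w -> h*w`` linear shared by all
channels).  Heads partition the token embedding.  Each stage carries a
residual connection ``x + attn(x)`` by default.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import nn
from .attention import ConfigurationError, PositionBiasTable, _attention_core
from .nn import Module, Tensor, as_tensor


def _ensure_batch(x: Tensor) -> Tuple[Tensor, bool]:
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    return x, False


class ChannelMHSA(Module):
    """Self-attention over channel tokens (no position embedding)."""

    def __init__(
        self,
        channels: int,
        spatial_tokens: int,
        n_heads: int = 4,
        residual: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        if spatial_tokens % n_heads:
            raise ConfigurationError(
                f"n_heads={n_heads} must divide the spatial embedding size {spatial_tokens}"
            )
        self.n_heads = n_heads
        self.residual = residual
        self.spatial_tokens = spatial_tokens
        d = spatial_tokens
        self.proj_q = nn.Linear(d, d, rng=rng)
        self.proj_k = nn.Linear(d, d, rng=rng)
        self.proj_v = nn.Linear(d, d, rng=rng)
        self.proj_out = nn.Linear(d, d, rng=rng)

    def forward(self, x, return_attention: bool = False):
        x, squeeze = _ensure_batch(as_tensor(x))
        n, c, h, w = x.shape
        if h * w != self.spatial_tokens:
            raise ConfigurationError(
                f"channel MHSA built for {self.spatial_tokens} spatial positions, got {h * w}"
            )
        tokens = x.reshape(n, c, h * w)
        out, attn = _attention_core(
            self.proj_q(tokens), self.proj_k(tokens), self.proj_v(tokens),
            bias=None, n_heads=self.n_heads, scale=None,
        )
        out = self.proj_out(out).reshape(n, c, h, w)
        if self.residual:
            out = out + x
        if squeeze:
            out = out.reshape(*out.shape[1:])
            attn = attn.reshape(*attn.shape[1:])
        return (out, attn) if return_attention else out


class SpatialMHSA(Module):
    """Self-attention over position tokens with absolute position bias.

    Logits are ``e_ij + p_ij`` where ``e`` is the scaled dot product of
    projected tokens and ``p`` is produced by a :class:`PositionBiasTable`
    contracted with the value-projected tokens.
    """

    def __init__(
        self,
        channels: int,
        n_tokens: int,
        n_heads: int = 4,
        residual: bool = True,
        use_position_bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        if channels % n_heads:
            raise ConfigurationError(f"n_heads={n_heads} must divide channels {channels}")
        self.n_heads = n_heads
        self.residual = residual
        self.n_tokens = n_tokens
        self.proj_q = nn.Linear(channels, channels, rng=rng)
        self.proj_k = nn.Linear(channels, channels, rng=rng)
        self.proj_v = nn.Linear(channels, channels, rng=rng)
        self.proj_out = nn.Linear(channels, channels, rng=rng)
        self.bias_table = (
            PositionBiasTable(n_tokens, channels // n_heads, rng=rng)
            if use_position_bias
            else None
        )

    def forward(self, x, return_attention: bool = False):
        x, squeeze = _ensure_batch(as_tensor(x))
        n, c, h, w = x.shape
        if h * w != self.n_tokens:
            raise ConfigurationError(
                f"spatial MHSA built for {self.n_tokens} tokens, got {h * w}"
            )
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, hw, C)
        q, k, v = self.proj_q(tokens), self.proj_k(tokens), self.proj_v(tokens)
        bias = None
        if self.bias_table is not None:
            vh = v.reshape(n, h * w, self.n_heads, c // self.n_heads).transpose(0, 2, 1, 3)
            bias = self.bias_table(vh)  # (N, heads, hw, hw)
        out, attn = _attention_core(q, k, v, bias=bias, n_heads=self.n_heads, scale=None)
        out = self.proj_out(out).transpose(0, 2, 1).reshape(n, c, h, w)
        if self.residual:
            out = out + x
        if squeeze:
            out = out.reshape(*out.shape[1:])
            attn = attn.reshape(*attn.shape[1:])
        return (out, attn) if return_attention else out


class CSA(Module):
    """Channel MHSA followed in series by spatial MHSA."""

    def __init__(
        self,
        channels: int,
        spatial_size: Tuple[int, int],
        n_heads: int = 4,
        residual: bool = True,
        use_channel: bool = True,
        use_spatial: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        h, w = spatial_size
        self.channel = (
            ChannelMHSA(channels, h * w, n_heads=n_heads, residual=residual, rng=rng)
            if use_channel
            else None
        )
        self.spatial = (
            SpatialMHSA(channels, h * w, n_heads=n_heads, residual=residual, rng=rng)
            if use_spatial
            else None
        )

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if self.channel is not None:
            x = self.channel(x)
        if self.spatial is not None:
            x = self.spatial(x)
        return x
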