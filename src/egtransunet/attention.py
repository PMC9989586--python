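"""Shared attention primitives.

Two building blocks live here:

* :func:`scaled_dot_attention` — multi-head scaled dot-product attention
  over token matrices, with an optional additive position bias applied to
  the logits before the softmax.
* :class:`DilatedSelfAttention` (DSA) — self-attention whose query/key/
  value embeddings are *dilated convolutions* rather than linear maps, so
  the token embeddings carry local spatial context while the attention
  aggregates globally.  Spatial size is preserved for any dilation.

Token layout is channel-first with row-major spatial flattening:
token index = row * width + column.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor, as_tensor


class ConfigurationError(ValueError):
    """Raised when a module is constructed with inconsistent settings."""


def _split_heads(t: Tensor, n_heads: int) -> Tensor:
    """(..., n, d) -> (..., heads, n, d/heads)."""
    *lead, n, d = t.shape
    return t.reshape(*lead, n, n_heads, d // n_heads).transpose(
        *range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2
    )


def _merge_heads(t: Tensor) -> Tensor:
    """(..., heads, n, hd) -> (..., n, heads*hd)."""
    *lead, h, n, hd = t.shape
    return t.transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2).reshape(
        *lead, n, h * hd
    )


def scaled_dot_attention(
    q,
    k,
    v,
    bias=None,
    n_heads: int = 1,
    scale: Optional[float] = None,
) -> Tuple[Tensor, Tensor]:
    """Multi-head scaled dot-product attention on token matrices.

    Parameters
    ----------
    q, k, v
        Token matrices of shape ``(n_q, d)`` / ``(n_k, d)`` / ``(n_k, d_v)``
        (a leading batch axis is also accepted).  ``q`` and ``k`` must share
        the embedding dimension; ``k`` and ``v`` must share the token count.
    bias
        Optional additive logit bias ``p`` of shape ``(n_q, n_k)`` or
        ``(n_heads, n_q, n_k)``, added to the scaled dot products before
        the softmax.
    n_heads
        Number of attention heads; must divide both embedding dimensions.
    scale
        Logit scale; defaults to ``1/sqrt(d_head)``.

    Returns
    -------
    (output, attention)
        ``output`` has ``q``'s token count and ``v``'s embedding dim;
        ``attention`` has shape ``(..., n_heads, n_q, n_k)`` and each row
        (fixed query) sums to 1.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    return _attention_core(q, k, v, bias, int(n_heads), scale)


class PositionBiasTable(Module):
    """Trainable absolute position bias for a fixed token grid.

    Stores one trainable vector ``a[i, j]`` per ordered token pair,
    shared across heads.  Given value-projected tokens ``xv`` the bias is
    ``p[h, i, j] = xv[h, i] . a[i, j]``, which enters the attention logits
    additively.
    """

    def __init__(self, n_tokens: int, head_dim: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_tokens = int(n_tokens)
        self.head_dim = int(head_dim)
        # small init so position bias starts near zero
        self.table = Parameter(
            rng.normal(0.0, 0.02, size=(n_tokens, n_tokens, head_dim)), decay=False
        )

    def forward(self, xv_heads: Tensor) -> Tensor:
        """Bias from value-projected tokens.

        ``xv_heads``: ``(..., n_heads, n_tokens, head_dim)`` ->
        bias ``(..., n_heads, n_tokens, n_tokens)``.
        """
        *lead, h, n, hd = xv_heads.shape
        if n != self.n_tokens or hd != self.head_dim:
            raise ConfigurationError(
                f"position table sized for ({self.n_tokens} tokens, dim {self.head_dim}), "
                f"got ({n}, {hd})"
            )
        # p[.., i, j] = xv[.., i, :] . a[i, j, :]  — batched matvec over i
        flat = xv_heads.reshape(-1, n, hd)
        rows = []
        for b in range(flat.shape[0]):
            xb = flat[b].reshape(n, hd, 1)            # (n, hd, 1)
            p = nn.matmul(self.table, xb)             # (n, n, 1) batched over i
            rows.append(p.reshape(1, n, n))
        out = nn.concat(rows, axis=0) if len(rows) > 1 else rows[0]
        return out.reshape(*lead, h, n, n)


def _attention_core(
    q: Tensor, k: Tensor, v: Tensor, bias, n_heads: int, scale: Optional[float]
) -> Tuple[Tensor, Tensor]:
    nq, d = q.shape[-2], q.shape[-1]
    nk, dk = k.shape[-2], k.shape[-1]
    if d != dk:
        raise ValueError(f"query dim {d} != key dim {dk}")
    if v.shape[-2] != nk:
        raise ValueError(f"key tokens {nk} != value tokens {v.shape[-2]}")
    if d % n_heads or v.shape[-1] % n_heads:
        raise ConfigurationError(f"n_heads={n_heads} must divide embedding dims {d}/{v.shape[-1]}")
    hd = d // n_heads
    if scale is None:
        scale = 1.0 / np.sqrt(hd)
    qh, kh, vh = (_split_heads(t, n_heads) for t in (q, k, v))
    logits = nn.matmul(qh, kh.transpose(*range(qh.ndim - 2), qh.ndim - 1, qh.ndim - 2)) * scale
    if bias is not None:
        bias = as_tensor(bias)
        if bias.shape[-2:] != (nq, nk):
            raise ConfigurationError(
                f"bias shape {bias.shape} incompatible with ({nq}, {nk}) logits"
            )
        logits = logits + bias
    attn = nn.softmax(logits, axis=-1)
    out = _merge_heads(nn.matmul(attn, vh))
    return out, attn


class DilatedSelfAttention(Module):
    """DSA block: dilated-convolution q/k/v embeddings + global attention.

    The input feature map is embedded three times with 3x3 dilated
    convolutions (stride 1, padding = dilation, no bias), flattened to
    ``n = h*w`` tokens, and mixed by a position-relevance attention map
    ``B``.  By default ``B`` is normalized over the *key* axis so every
    output token's mixing weights sum to 1; ``axis="printed"`` instead
    normalizes over queries (softmax over the first index), the
    alternative reading of the defining formula.  No logit scale is
    applied by default; ``scaled=True`` enables ``1/sqrt(c)``.
    """

    def __init__(
        self,
        channels: int,
        dilation: int,
        axis: str = "key",
        scaled: bool = False,
        out_projection: bool = True,
        residual: bool = False,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if dilation < 1:
            raise ConfigurationError(f"dilation must be positive, got {dilation}")
        if axis not in ("key", "printed"):
            raise ConfigurationError(f"axis must be 'key' or 'printed', got {axis!r}")
        rng = rng or np.random.default_rng()
        self.dilation = int(dilation)
        self.axis = axis
        self.scaled = scaled
        self.residual = residual
        conv = lambda: nn.Conv2d(
            channels, channels, 3, padding=dilation, dilation=dilation, bias=False, rng=rng
        )
        self.proj_q, self.proj_k, self.proj_v = conv(), conv(), conv()
        self.proj_out = (
            nn.Conv2d(channels, channels, 1, bias=bias, rng=rng) if out_projection else None
        )

    def forward(self, x: Tensor, return_attention: bool = False):
        x = as_tensor(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        q = self.proj_q(x).reshape(n, c, h * w).transpose(0, 2, 1)   # M: (N, hw, c)
        k = self.proj_k(x).reshape(n, c, h * w).transpose(0, 2, 1)   # N
        t = self.proj_v(x).reshape(n, c, h * w).transpose(0, 2, 1)   # T
        logits = nn.matmul(q, k.transpose(0, 2, 1))                  # (N, hw, hw): M_i . N_j
        if self.scaled:
            logits = logits * (1.0 / np.sqrt(c))
        attn = nn.softmax(logits, axis=-1 if self.axis == "key" else -2)
        out = nn.matmul(attn, t)                                     # B . T
        out = out.transpose(0, 2, 1).reshape(n, c, h, w)
        if self.proj_out is not None:
            out = self.proj_out(out)
        if self.residual:
            out = out + x
        if squeeze:
            out = out.reshape(*out.shape[1:])
            attn = attn.reshape(*attn.shape[1:])
        return (out, attn) if return_attention else out


def dsa_forward(x, dilation: int, rng: Optional[np.random.Generator] = None) -> Tensor:
    """Functional DSA with freshly initialized embeddings (convenience)."""
    x = as_tensor(x)
    channels = x.shape[0] if x.ndim == 3 else x.shape[1]
    return DilatedSelfAttention(channels, dilation, rng=rng)(x)
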