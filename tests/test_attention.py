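"""Attention primitives vs. explicit double-loop references."""

import numpy as np
import pytest

from egtransunet import (
    ConfigurationError,
    DilatedSelfAttention,
    PositionBiasTable,
    scaled_dot_attention,
)
from egtransunet.nn import Tensor


def loop_attention(q, k, v, bias=None, scale=None):
    """O(n^2 d) single-head reference: explicit exp / normalize / weighted sum."""
    nq, d = q.shape
    nk = k.shape[0]
    scale = scale if scale is not None else 1.0 / np.sqrt(d)
    attn = np.zeros((nq, nk))
    for i in range(nq):
        logits = np.array([
            sum(q[i, t] * k[j, t] for t in range(d)) * scale
            + (bias[i, j] if bias is not None else 0.0)
            for j in range(nk)
        ])
        e = np.exp(logits - logits.max())
        attn[i] = e / e.sum()
    out = np.zeros((nq, v.shape[1]))
    for i in range(nq):
        for j in range(nk):
            out[i] += attn[i, j] * v[j]
    return out, attn


def test_single_token_attention_is_identity_on_value():
    q = np.array([[0.3, -1.2]])
    k = np.array([[2.0, 0.5]])
    v = np.array([[7.0, -3.0]])
    out, attn = scaled_dot_attention(q, k, v)
    assert np.allclose(attn.data, [[[1.0]]])
    assert np.allclose(out.data, v)


def test_identical_keys_give_uniform_attention():
    rng = np.random.default_rng(0)
    q = rng.normal(size=(3, 4))
    k = np.tile(rng.normal(size=(1, 4)), (2, 1))  # two identical key tokens
    v = rng.normal(size=(2, 4))
    _, attn = scaled_dot_attention(q, k, v)
    assert np.allclose(attn.data, 0.5)


def test_matches_loop_oracle_single_head():
    rng = np.random.default_rng(42)
    q, k, v = (rng.normal(size=(6, 4)) for _ in range(3))
    out, attn = scaled_dot_attention(q, k, v, n_heads=1)
    ref_out, ref_attn = loop_attention(q, k, v)
    assert np.abs(out.data - ref_out).max() < 1e-5
    assert np.abs(attn.data[0] - ref_attn).max() < 1e-5


def test_matches_loop_oracle_with_bias_and_heads():
    rng = np.random.default_rng(43)
    q, k, v = (rng.normal(size=(5, 8)) for _ in range(3))
    bias = rng.normal(size=(5, 5))
    out, attn = scaled_dot_attention(q, k, v, bias=bias, n_heads=2)
    # per-head loop reference over the split embeddings
    for h in range(2):
        sl = slice(4 * h, 4 * h + 4)
        ref_out, ref_attn = loop_attention(q[:, sl], k[:, sl], v[:, sl], bias=bias)
        assert np.abs(attn.data[h] - ref_attn).max() < 1e-5
        assert np.abs(out.data[:, sl] - ref_out).max() < 1e-5


def test_rows_sum_to_one_many_configs():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n, d = int(rng.integers(1, 9)), int(rng.integers(1, 5)) * 2
        q, k, v = (rng.normal(size=(n, d)) for _ in range(3))
        _, attn = scaled_dot_attention(q, k, v, n_heads=2)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)


def test_permutation_equivariance_of_keys_and_values():
    """Permuting key/value tokens together leaves every output unchanged."""
    rng = np.random.default_rng(8)
    q, k, v = rng.normal(size=(4, 6)), rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
    out, _ = scaled_dot_attention(q, k, v, n_heads=2)
    perm = rng.permutation(5)
    out_p, _ = scaled_dot_attention(q, k[perm], v[perm], n_heads=2)
    assert np.allclose(out.data, out_p.data, atol=1e-12)


def test_dimension_errors():
    q = np.zeros((3, 4))
    with pytest.raises(ValueError):
        scaled_dot_attention(q, np.zeros((3, 5)), np.zeros((3, 4)))
    with pytest.raises(ValueError):
        scaled_dot_attention(q, np.zeros((2, 4)), np.zeros((3, 4)))
    with pytest.raises(ConfigurationError):
        scaled_dot_attention(q, q, q, n_heads=3)


def test_position_bias_table_contract():
    rng = np.random.default_rng(9)
    table = PositionBiasTable(4, 3, rng=rng)
    xv = Tensor(rng.normal(size=(2, 4, 3)))  # (heads, n, hd)
    p = table(xv)
    assert p.shape == (2, 4, 4)
    # termwise check: p[h, i, j] = xv[h, i] . a[i, j]
    for h in range(2):
        for i in range(4):
            for j in range(4):
                ref = float(xv.data[h, i] @ table.table.data[i, j])
                assert abs(p.data[h, i, j] - ref) < 1e-12
    with pytest.raises(ConfigurationError):
        table(Tensor(rng.normal(size=(2, 5, 3))))


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("dilation", [1, 2, 3])
def test_dsa_is_shape_preserving(dilation):
    rng = np.random.default_rng(10)
    dsa = DilatedSelfAttention(4, dilation, rng=rng)
    x = rng.normal(size=(4, 8, 8))
    assert dsa(x).shape == (4, 8, 8)


def test_dsa_attention_normalized_on_both_axis_settings():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(4, 8, 8))
    for axis, sum_axis in (("key", -1), ("printed", -2)):
        dsa = DilatedSelfAttention(4, 2, axis=axis, rng=rng)
        _, attn = dsa(Tensor(x), return_attention=True)
        assert np.allclose(attn.data.sum(axis=sum_axis), 1.0, atol=1e-6)


def test_dsa_matches_explicit_loop_reference():
    """Frozen convolution weights: output equals materialized M, N, T and B.T."""
    from scipy.signal import correlate2d

    rng = np.random.default_rng(12)
    c, h, w = 2, 4, 4
    dsa = DilatedSelfAttention(c, dilation=2, out_projection=False, rng=rng)
    x = rng.normal(size=(c, h, w))

    def embed(conv):
        # dilated 3x3 correlation, padding=dilation, per output channel
        out = np.zeros((c, h, w))
        for o in range(c):
            for ci in range(c):
                kernel = np.zeros((5, 5))
                kernel[::2, ::2] = conv.weight.data[o, ci]  # dilate the 3x3 taps
                out[o] += correlate2d(x[ci], kernel, mode="same")
        return out

    m = embed(dsa.proj_q).reshape(c, -1).T  # (n, c) row-major tokens
    nn_ = embed(dsa.proj_k).reshape(c, -1).T
    t = embed(dsa.proj_v).reshape(c, -1).T
    n = h * w
    b = np.zeros((n, n))
    for i in range(n):
        logits = np.array([float(m[i] @ nn_[j]) for j in range(n)])
        e = np.exp(logits - logits.max())
        b[i] = e / e.sum()
    ref = (b @ t).T.reshape(c, h, w)
    out = dsa(x)
    assert np.abs(out.data - ref).max() < 1e-5


def test_dsa_rejects_bad_configuration():
    with pytest.raises(ConfigurationError):
        DilatedSelfAttention(4, 0)
    with pytest.raises(ConfigurationError):
        DilatedSelfAttention(4, 2, axis="rows")
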