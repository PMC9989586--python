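"""Minimal reverse-mode autodiff and neural-network core on numpy.

Everything in this package computes on :class:`Tensor`, a thin wrapper
around a ``numpy.ndarray`` that records the operations applied to it and
can backpropagate gradients through them.  The op set is exactly what the
segmentation network needs: broadcasting arithmetic, matmul, (dilated)
2-D convolution, batch normalization, bilinear upsampling, softmax and
elementwise nonlinearities.

Arrays are kept in float64 throughout; the network is small enough that
the extra precision is cheap and it keeps oracle comparisons tight.

A process-global multiply–accumulate (MAC) counter can be armed with
:func:`count_macs`; convolution and matmul then record their arithmetic
cost, which is how model complexity is measured.
"""

from __future__ import annotations

import contextlib
from collections import OrderedDict
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "UpsampleBilinear2d",
    "SGD",
    "count_macs",
    "as_tensor",
    "concat",
    "matmul",
    "softmax",
    "kaiming_normal",
]

# --------------------------------------------------------------------------
# MAC counting
# --------------------------------------------------------------------------

_MAC_COUNTER: Optional[list] = None


@contextlib.contextmanager
def count_macs() -> Iterator[list]:
    """Context manager arming a global multiply–accumulate counter.

    Yields a one-element list; after the block, ``counter[0]`` holds the
    number of MACs executed by conv/matmul/upsample ops inside it.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


# --------------------------------------------------------------------------
# Tensor
# --------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with reverse-mode automatic differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd ------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(go, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(go):
            if self.requires_grad:
                self._accum(-go)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(go * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-go * self.data / (other.data ** 2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(go):
            if self.requires_grad:
                self._accum(go * e * self.data ** (e - 1.0))

        return Tensor._make(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(go):
            if self.requires_grad:
                self._accum(go.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(go):
            if self.requires_grad:
                self._accum(go.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        assert self.ndim == 2
        return self.transpose(1, 0)

    def __getitem__(self, idx):
        def backward(go):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, go)
                self._accum(g)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(go):
            if not self.requires_grad:
                return
            g = go
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(go):
            if self.requires_grad:
                self._accum(go * mask)

        # np.maximum (not where) so NaN propagates instead of being silenced
        return Tensor._make(np.maximum(self.data, 0.0), (self,), backward)

    def sigmoid(self):
        # numerically stable in both tails
        pos = self.data >= 0
        out_data = np.empty_like(self.data)
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        out_data[~pos] = e / (1.0 + e)

        def backward(go):
            if self.requires_grad:
                self._accum(go * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(go):
            if self.requires_grad:
                self._accum(go * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(go):
            if self.requires_grad:
                self._accum(go / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(go):
            if self.requires_grad:
                self._accum(go * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# --------------------------------------------------------------------------
# Free functions: matmul, softmax, concat
# --------------------------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    # MAC cost: batch * n * k * m
    batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
    _add_macs(batch * out_data.shape[-2] * a.data.shape[-1] * out_data.shape[-1])

    def backward(go):
        if a.requires_grad:
            ga = np.matmul(go, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), go)
            b._accum(_unbroadcast(gb, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(go):
        if x.requires_grad:
            dot = (go * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (go - dot))

    return Tensor._make(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(go):
        pieces = np.split(go, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    return Tensor._make(out_data, tuple(tensors), backward)


# --------------------------------------------------------------------------
# Structured ops: conv2d, batch norm, bilinear upsampling
# --------------------------------------------------------------------------


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, symmetric padding.

    Implemented as a sum over kernel taps of strided-slice einsums; the
    backward pass mirrors each tap.  Supports arbitrary dilation.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    s, p, d = int(stride), int(padding), int(dilation)
    hout = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    wout = (wd + 2 * p - d * (kw - 1) - 1) // s + 1
    if hout < 1 or wout < 1:
        raise ValueError("conv2d: spatial size smaller than dilated kernel extent")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    out_data = np.zeros((n, o, hout, wout))
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki * d : ki * d + s * hout : s, kj * d : kj * d + s * wout : s]
            out_data += np.einsum("oc,nchw->nohw", w.data[:, :, ki, kj], xs, optimize=True)
    _add_macs(kh * kw * c * o * hout * wout * n)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(go):
        if b is not None and b.requires_grad:
            b._accum(go.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for ki in range(kh):
            for kj in range(kw):
                sl = np.s_[:, :, ki * d : ki * d + s * hout : s, kj * d : kj * d + s * wout : s]
                if need_w:
                    gw[:, :, ki, kj] = np.einsum(
                        "nohw,nchw->oc", go, xp[sl], optimize=True
                    )
                if need_x:
                    gxp[sl] += np.einsum(
                        "oc,nohw->nchw", w.data[:, :, ki, kj], go, optimize=True
                    )
        if need_w:
            w._accum(gw)
        if need_x:
            gx = gxp[:, :, p : p + h, p : p + wd] if p else gxp
            x._accum(gx)

    return Tensor._make(out_data, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used, so the
    forward pass is a deterministic affine map.
    """
    x = as_tensor(x)
    g = gamma.data.reshape(1, -1, 1, 1)
    bt = beta.data.reshape(1, -1, 1, 1)
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        cnt = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        # unbiased variance for the running buffer, as is conventional
        running_var *= 1.0 - momentum
        running_var += momentum * (v * cnt / max(cnt - 1, 1))
    else:
        m, v = running_mean, running_var
    invstd = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(1, -1, 1, 1)) * invstd.reshape(1, -1, 1, 1)
    out_data = g * xhat + bt

    def backward(go):
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        istd = invstd.reshape(1, -1, 1, 1)
        dxhat = go * g
        if training:
            cnt = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = istd / cnt * (cnt * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        else:
            gx = dxhat * istd
        x._accum(gx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    a[np.arange(n_out), i0] += 1.0 - t
    a[np.arange(n_out), i1] += t
    return a


def upsample_bilinear2d(x: Tensor, scale: int = 2) -> Tensor:
    """Bilinear 2x (or other integer-factor) upsampling of NCHW tensors."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ah = _interp_matrix(h * scale, h)
    aw = _interp_matrix(w * scale, w)
    out_data = np.matmul(np.matmul(ah, x.data), aw.T)
    _add_macs(n * c * (h * scale * h * w + h * scale * w * w * scale))

    def backward(go):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(ah.T, go), aw))

    return Tensor._make(out_data, (x,), backward)


# --------------------------------------------------------------------------
# Modules
# --------------------------------------------------------------------------


class Parameter(Tensor):
    """A trainable tensor.  `decay` marks it eligible for weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = bool(decay)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-style initialization for ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Lightweight module base: parameter traversal, train/eval, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (prefix + name, val)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def _named_buffers(self, prefix: str = "") -> Iterator[tuple]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield (prefix + name, val)
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, buf in self._named_buffers():
            state["buffer:" + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != np.shape(value):
                    raise ValueError(f"shape mismatch loading {key}")
                p.data = np.asarray(value, dtype=np.float64).copy()


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )

    def named_parameters(self, prefix: str = ""):
        yield (prefix + "weight", self.weight)
        if self.bias is not None:
            yield (prefix + "bias", self.bias)


class Linear(Module):
    """Affine map applied to the last axis (a per-token linear layer)."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(kaiming_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features), decay=False) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out

    def named_parameters(self, prefix: str = ""):
        yield (prefix + "weight", self.weight)
        if self.bias is not None:
            yield (prefix + "bias", self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features), decay=False)
        self.beta = Parameter(np.zeros(num_features), decay=False)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class UpsampleBilinear2d(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return upsample_bilinear2d(x, self.scale)


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay (L2, coupled) is applied only to parameters whose
    ``decay`` flag is set — convolution and linear weights, not
    normalization scales or biases.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
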