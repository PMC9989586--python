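"""Gradient checks and contracts for the numpy autodiff core."""

import numpy as np
import pytest

from egtransunet import nn
from egtransunet.nn import Tensor


def numerical_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of one array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_input_grad(op, x0, tol=1e-6):
    """Compare autodiff dL/dx with finite differences, L = weighted sum."""
    rng = np.random.default_rng(0)
    t = Tensor(x0.copy(), requires_grad=True)
    out = op(t)
    w = rng.normal(size=out.shape)
    (out * Tensor(w)).sum().backward()

    def scalar(x):
        return float((op(Tensor(x)).data * w).sum())

    num = numerical_grad(scalar, x0.copy())
    assert np.allclose(t.grad, num, atol=tol), np.abs(t.grad - num).max()


@pytest.mark.parametrize(
    "op",
    [
        lambda t: t.relu(),
        lambda t: t.sigmoid(),
        lambda t: (t * t).exp(),
        lambda t: (t * t + 0.1).log(),
        lambda t: nn.softmax(t, axis=-1),
        lambda t: t.reshape(6, 4),
        lambda t: t.transpose(0, 2, 1, 3) if t.ndim == 4 else t.transpose(1, 0),
        lambda t: t.mean(axis=0),
        lambda t: (t + 2.0) * t - t / 3.0,
    ],
    ids=["relu", "sigmoid", "exp", "log", "softmax", "reshape", "transpose", "mean", "arith"],
)
def test_elementwise_and_shape_grads(op):
    x = np.random.default_rng(1).normal(size=(2, 3, 2, 2))
    check_input_grad(op, x)


def test_matmul_grads_both_sides():
    rng = np.random.default_rng(2)
    a0, b0 = rng.normal(size=(3, 4)), rng.normal(size=(4, 5))
    a, b = Tensor(a0, requires_grad=True), Tensor(b0, requires_grad=True)
    w = rng.normal(size=(3, 5))
    (nn.matmul(a, b) * Tensor(w)).sum().backward()
    assert np.allclose(a.grad, w @ b0.T)
    assert np.allclose(b.grad, a0.T @ w)


def test_batched_matmul_grad():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(2, 3, 4))
    b = Tensor(rng.normal(size=(2, 4, 3)))
    check_input_grad(lambda t: nn.matmul(t, b), x)


@pytest.mark.parametrize("stride,padding,dilation", [(1, 1, 1), (2, 1, 1), (1, 2, 2), (1, 3, 3)])
def test_conv2d_grads(stride, padding, dilation):
    rng = np.random.default_rng(4)
    x0 = rng.normal(size=(2, 3, 8, 8))
    w0 = rng.normal(size=(4, 3, 3, 3))
    b0 = rng.normal(size=4)
    wt = Tensor(w0, requires_grad=True)
    bt = Tensor(b0, requires_grad=True)

    def op(t):
        return nn.conv2d(t, wt, bt, stride=stride, padding=padding, dilation=dilation)

    check_input_grad(op, x0, tol=1e-5)
    # weight gradient
    x = Tensor(x0)
    out = nn.conv2d(x, wt, bt, stride=stride, padding=padding, dilation=dilation)
    probe = np.random.default_rng(5).normal(size=out.shape)
    wt.grad = None
    (out * Tensor(probe)).sum().backward()

    def scalar_w(w):
        o = nn.conv2d(x, Tensor(w), bt, stride=stride, padding=padding, dilation=dilation)
        return float((o.data * probe).sum())

    num = numerical_grad(scalar_w, w0.copy())
    assert np.allclose(wt.grad, num, atol=1e-5)


def test_conv2d_matches_scipy_reference():
    """Cross-check a plain (stride 1, dil 1) convolution against scipy."""
    from scipy.signal import correlate2d

    rng = np.random.default_rng(6)
    x = rng.normal(size=(1, 2, 7, 7))
    w = rng.normal(size=(3, 2, 3, 3))
    out = nn.conv2d(Tensor(x), Tensor(w), padding=1).data
    ref = np.zeros_like(out)
    for o in range(3):
        for c in range(2):
            ref[0, o] += correlate2d(x[0, c], w[o, c], mode="same")
    assert np.allclose(out, ref, atol=1e-10)


def test_batchnorm_train_grad_and_eval_determinism():
    rng = np.random.default_rng(7)
    x0 = rng.normal(size=(3, 2, 4, 4))
    bn = nn.BatchNorm2d(2)
    bn.gamma.data = rng.normal(size=2)
    bn.beta.data = rng.normal(size=2)

    def op(t):
        # reset running buffers so repeated calls see identical state
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
        return bn(t)

    check_input_grad(op, x0, tol=1e-5)
    bn.eval()
    y1, y2 = bn(Tensor(x0)).data, bn(Tensor(x0)).data
    assert np.array_equal(y1, y2)


def test_upsample_bilinear_grad_and_shape():
    rng = np.random.default_rng(8)
    x0 = rng.normal(size=(1, 2, 3, 5))
    out = nn.upsample_bilinear2d(Tensor(x0), 2)
    assert out.shape == (1, 2, 6, 10)
    check_input_grad(lambda t: nn.upsample_bilinear2d(t, 2), x0)
    # constant fields are preserved exactly by interpolation
    const = nn.upsample_bilinear2d(Tensor(np.full((1, 1, 4, 4), 3.5)), 2)
    assert np.allclose(const.data, 3.5)


def test_concat_and_getitem_grads():
    rng = np.random.default_rng(9)
    x0 = rng.normal(size=(2, 3, 2, 2))
    other = Tensor(rng.normal(size=(2, 2, 2, 2)))
    check_input_grad(lambda t: nn.concat([t, other], axis=1), x0)
    check_input_grad(lambda t: t[:, 1:3], x0)


def test_sgd_momentum_weight_decay_step():
    p = nn.Parameter(np.array([1.0, -2.0]), decay=True)
    q = nn.Parameter(np.array([0.5]), decay=False)
    opt = nn.SGD([p, q], lr=0.1, momentum=0.9, weight_decay=0.01)
    p.grad, q.grad = np.array([0.3, 0.3]), np.array([0.2])
    opt.step()
    # v = g + wd*p for decaying params; p -= lr*v
    assert np.allclose(p.data, np.array([1.0, -2.0]) - 0.1 * (np.array([0.3, 0.3]) + 0.01 * np.array([1.0, -2.0])))
    assert np.allclose(q.data, 0.5 - 0.1 * 0.2)
    p.grad, q.grad = np.zeros(2), np.zeros(1)
    prev = p.data.copy()
    opt.step()  # momentum keeps moving even with zero grad
    assert not np.allclose(p.data, prev)


def test_mac_counter_conv_closed_form():
    """MACs of one k x k conv equal k^2 * Cin * Cout * Hout * Wout."""
    x = Tensor(np.zeros((1, 3, 10, 10)))
    w = Tensor(np.zeros((8, 3, 3, 3)))
    with nn.count_macs() as macs:
        nn.conv2d(x, w, padding=1)
    assert macs[0] == 3 * 3 * 3 * 8 * 10 * 10


def test_state_dict_roundtrip():
    rng = np.random.default_rng(10)
    conv = nn.Conv2d(2, 3, 3, padding=1, rng=rng)
    bn = nn.BatchNorm2d(3)

    class Block(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv, self.bn = conv, bn

        def forward(self, x):
            return self.bn(self.conv(x))

    block = Block()
    x = Tensor(rng.normal(size=(2, 2, 5, 5)))
    block(x)  # populate running stats
    state = block.state_dict()
    block2 = Block()
    block2.load_state_dict(state)
    block.eval(), block2.eval()
    assert np.array_equal(block(x).data, block2(x).data)
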