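"""Gradient correctness of the tensor core against brute-force oracles.

Convolution forward/backward are checked against explicit float64 loops;
the remaining ops against central finite differences on small tensors.
"""

import numpy as np
import pytest

from macgan import nn
from macgan.nn.tensor import (Tensor, batch_norm, conv3d, maxpool3d, sigmoid,
                              softmax, tmax, tmean, tsum, upsample_linear3d)


def brute_conv3d(x, w, b, s, p):
    x, w = x.astype(np.float64), w.astype(np.float64)
    n, ci, _, _, _ = x.shape
    co = w.shape[0]
    kd, kh, kw = w.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p[0],) * 2, (p[1],) * 2, (p[2],) * 2))
    do = (xp.shape[2] - kd) // s[0] + 1
    ho = (xp.shape[3] - kh) // s[1] + 1
    wo = (xp.shape[4] - kw) // s[2] + 1
    out = np.zeros((n, co, do, ho, wo))
    for ni in range(n):
        for c in range(co):
            for d in range(do):
                for h in range(ho):
                    for v in range(wo):
                        win = xp[ni, :, d * s[0]:d * s[0] + kd,
                                 h * s[1]:h * s[1] + kh,
                                 v * s[2]:v * s[2] + kw]
                        out[ni, c, d, h, v] = (win * w[c]).sum()
    if b is not None:
        out += b.astype(np.float64)[None, :, None, None, None]
    return out


@pytest.mark.parametrize("stride,padding,kernel", [
    ((1, 1, 1), (1, 1, 1), (3, 3, 3)),
    ((2, 2, 2), (1, 1, 1), (3, 3, 3)),
    ((1, 1, 1), (0, 1, 1), (1, 3, 3)),   # the 2-D-conv-as-3-D case
    ((1, 1, 1), (0, 0, 0), (1, 1, 1)),
])
def test_conv3d_matches_brute_force(stride, padding, kernel, rng):
    x = rng.normal(size=(2, 3, 4, 6, 6)).astype(np.float32)
    w = rng.normal(size=(4, 3) + kernel).astype(np.float32) * 0.3
    b = rng.normal(size=4).astype(np.float32)
    out = conv3d(Tensor(x), Tensor(w), Tensor(b), stride=stride, padding=padding)
    ref = brute_conv3d(x, w, b, stride, padding)
    np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)


def test_conv3d_gradients_match_brute_force(rng):
    """∂loss/∂x and ∂loss/∂w for loss = Σ conv(x, w) equal explicit sums."""
    x = rng.normal(size=(1, 2, 4, 5, 5)).astype(np.float32)
    w = rng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32) * 0.3
    s, p = (1, 1, 1), (1, 1, 1)
    xt = Tensor(x, requires_grad=True)
    wt = Tensor(w, requires_grad=True)
    out = conv3d(xt, wt, None, stride=s, padding=p)
    out.backward(np.ones_like(out.data))
    # with unit upstream gradient, grad_x[v] = Σ of kernel taps that touch v
    gx = np.zeros(x.shape)
    gw = np.zeros(w.shape)
    g = np.ones(out.shape)
    xp = np.pad(x.astype(np.float64),
                ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    for c in range(w.shape[0]):
        for a in range(3):
            for bb in range(3):
                for cc in range(3):
                    for d in range(out.shape[2]):
                        for h in range(out.shape[3]):
                            for v in range(out.shape[4]):
                                di, hi, wi = d + a - 1, h + bb - 1, v + cc - 1
                                if (0 <= di < x.shape[2] and 0 <= hi < x.shape[3]
                                        and 0 <= wi < x.shape[4]):
                                    gx[0, :, di, hi, wi] += g[0, c, d, h, v] * w[c, :, a, bb, cc]
                    gw[c, :, a, bb, cc] = (
                        g[:, c, :, :, :, None].transpose(0, 4, 1, 2, 3)
                        * xp[:, :, a:a + out.shape[2], bb:bb + out.shape[3],
                             cc:cc + out.shape[4]]).sum(axis=(0, 2, 3, 4))
    np.testing.assert_allclose(xt.grad, gx, rtol=1e-4, atol=1e-4)
    np.testing.assert_allclose(wt.grad, gw, rtol=1e-4, atol=1e-4)


def _numgrad(f, x, eps=1e-2):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp_, xm = x.copy(), x.copy()
        xp_[i] += eps
        xm[i] -= eps
        g[i] = (f(xp_) - f(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize("op,shape", [
    (lambda t: tsum(sigmoid(t) * t), (2, 3, 4)),
    (lambda t: tsum(maxpool3d(t) * 1.5), (1, 2, 4, 4, 4)),
    (lambda t: tsum(upsample_linear3d(t) * 0.5), (1, 2, 2, 3, 2)),
    (lambda t: tsum(tmax(t, axis=1) + tmean(t, axis=1)), (2, 4, 3)),
    (lambda t: tsum(softmax(t) * Tensor(np.array([1.0, -2.0, 0.5], np.float32))), (3,)),
])
def test_op_gradients_match_finite_differences(op, shape, rng):
    x = rng.normal(size=shape).astype(np.float32)
    xt = Tensor(x, requires_grad=True)
    op(xt).backward()
    num = _numgrad(lambda a: float(op(Tensor(a)).data), x)
    np.testing.assert_allclose(xt.grad, num, rtol=2e-2, atol=2e-2)


def test_batchnorm_train_gradient_matches_finite_differences(rng):
    x = rng.normal(size=(2, 2, 2, 3, 2)).astype(np.float32)
    gamma = np.array([1.3, 0.7], np.float32)
    beta = np.array([0.1, -0.2], np.float32)

    def run(xa, ga=gamma, ba=beta):
        mu = xa.mean(axis=(0, 2, 3, 4))
        var = xa.var(axis=(0, 2, 3, 4))
        out = batch_norm(Tensor(xa), Tensor(ga), Tensor(ba), mu, var,
                         batch_stats=True)
        return tsum(out * sigmoid(out))

    xt = Tensor(x, requires_grad=True)
    gt = Tensor(gamma, requires_grad=True)
    mu, var = x.mean(axis=(0, 2, 3, 4)), x.var(axis=(0, 2, 3, 4))
    out = batch_norm(xt, gt, Tensor(beta), mu, var, batch_stats=True)
    tsum(out * sigmoid(out)).backward()
    np.testing.assert_allclose(
        xt.grad, _numgrad(lambda a: float(run(a).data), x), rtol=3e-2, atol=3e-2)
    np.testing.assert_allclose(
        gt.grad, _numgrad(lambda a: float(run(x, ga=a).data), gamma),
        rtol=3e-2, atol=3e-2)


def test_backward_accumulates_through_shared_subexpressions(rng):
    x = Tensor(rng.normal(size=(3,)).astype(np.float32), requires_grad=True)
    y = tsum(x * x + x * 2.0)       # dy/dx = 2x + 2
    y.backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 2, rtol=1e-5)


def test_no_grad_suppresses_graph(rng):
    x = Tensor(rng.normal(size=(3,)).astype(np.float32), requires_grad=True)
    with nn.no_grad():
        y = tsum(x * x)
    assert y._parents == () and y._backward is None


def test_adamw_decoupled_weight_decay_shrinks_ungradded_direction():
    # a parameter with zero gradient still decays toward zero
    p = Tensor(np.array([10.0], np.float32), requires_grad=True)
    p.grad = np.zeros(1, np.float32)
    opt = nn.AdamW([p], lr=0.1, weight_decay=0.5)
    before = p.data.copy()
    opt.step()
    assert 0 < p.data[0] < before[0]
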