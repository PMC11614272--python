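"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op set is deliberately small — exactly what the
segmentation networks need: broadcast arithmetic, reductions, reshaping and
concatenation, 3-D convolution (strided, anisotropic kernels), 2×2×2 max
pooling, linear-interpolation upsampling, and the usual pointwise
nonlinearities.  Everything runs in float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor", "as_tensor", "relu", "sigmoid", "exp", "log", "powc",
    "tsum", "tmean", "tmax", "reshape", "concatenate", "stack", "softmax",
    "linear", "conv3d", "maxpool3d", "upsample_linear3d", "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _add_back)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * powc(as_tensor(other), -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * powc(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts):
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward):
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _add_back(a, b, out_g, _data):
    if a.requires_grad or a._parents:
        a._accum(_unbroadcast(out_g, a.shape))
    if b.requires_grad or b._parents:
        b._accum(_unbroadcast(out_g, b.shape))


def _mul_back(a, b, out_g, _data):
    if a.requires_grad or a._parents:
        a._accum(_unbroadcast(out_g * b.data, a.shape))
    if b.requires_grad or b._parents:
        b._accum(_unbroadcast(out_g * a.data, b.shape))


def _binary(a, b, fwd, back):
    a, b = as_tensor(a), as_tensor(b)
    data = fwd(a.data, b.data)
    return _make(data, (a, b), lambda g, a=a, b=b, d=data: back(a, b, g, d))


# -- pointwise ----------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.maximum(x.data, 0.0)

    def back(g):
        x._accum(g * (x.data > 0))

    return _make(data, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = expit(x.data)

    def back(g, d=data):
        x._accum(g * d * (1.0 - d))

    return _make(data, (x,), back)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.exp(x.data)

    def back(g, d=data):
        x._accum(g * d)

    return _make(data, (x,), back)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.log(x.data)

    def back(g):
        x._accum(g / x.data)

    return _make(data, (x,), back)


def powc(x: Tensor, p: float) -> Tensor:
    """Elementwise power with a constant exponent."""
    x = as_tensor(x)
    data = np.power(x.data, p)

    def back(g):
        x._accum(g * p * np.power(x.data, p - 1.0))

    return _make(data, (x,), back)


# -- reductions ---------------------------------------------------------
def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(g, x.shape))

    return _make(data, (x,), back)


def tmean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tmax(x: Tensor, axis, keepdims=False) -> Tensor:
    """Max-reduction; ties share the gradient equally."""
    x = as_tensor(x)
    data = x.data.max(axis=axis, keepdims=keepdims)

    def back(g):
        m = x.data.max(axis=axis, keepdims=True)
        mask = (x.data == m).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        gk = g if keepdims else np.expand_dims(g, axis)
        x._accum(mask * gk)

    return _make(data, (x,), back)


# -- shape ops ----------------------------------------------------------
def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    data = x.data.reshape(shape)

    def back(g):
        x._accum(g.reshape(x.shape))

    return _make(data, (x,), back)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def back(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gs in zip(tensors, splits):
            if t.requires_grad or t._parents:
                t._accum(gs)

    return _make(data, tensors, back)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad or t._parents:
                t._accum(np.take(g, i, axis=axis))

    return _make(data, tensors, back)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis (used for the 3 fusion-weight logits)."""
    x = as_tensor(x)
    shifted = x - float(x.data.max())
    e = exp(shifted)
    return e / tsum(e, axis=-1, keepdims=True)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` for 2-D ``x`` [N, Fin] and ``w`` [Fout, Fin]."""
    x, w = as_tensor(x), as_tensor(w)
    data = x.data @ w.data.T
    if b is not None:
        data = data + b.data

    def back(g):
        if x.requires_grad or x._parents:
            x._accum(g @ w.data)
        if w.requires_grad or w._parents:
            w._accum(g.T @ x.data)
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, back)


# -- convolution --------------------------------------------------------
def _triple(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


def _offset_slices(xp_shape, k, s):
    """Output spatial sizes and the shifted-slice map of a correlation."""
    dims = [(xp_shape[2 + i] - k[i]) // s[i] + 1 for i in range(3)]

    def sl(off):
        return tuple(slice(off[i], off[i] + (dims[i] - 1) * s[i] + 1, s[i])
                     for i in range(3))

    return dims, sl


_CONV_BUDGET = 1 << 26  # elements per column-buffer slab (≈256 MB float32)


def _im2col_slab(xp, k, s, dims, d0, d1):
    """Column buffer for output depths [d0, d1): [N, Cin·kk, (d1−d0)·Ho·Wo].

    Built from contiguous shifted slices — far cheaper on CPU than
    gathering an 8-D sliding-window view.
    """
    n, cin = xp.shape[:2]
    _, ho, wo = dims
    dlen = d1 - d0
    kk = int(np.prod(k))
    buf = np.empty((n, cin, kk, dlen, ho, wo), dtype=np.float32)
    idx = 0
    for dd in range(k[0]):
        for dh in range(k[1]):
            for dw in range(k[2]):
                dsl = slice(d0 * s[0] + dd, d0 * s[0] + dd + (dlen - 1) * s[0] + 1, s[0])
                hsl = slice(dh, dh + (ho - 1) * s[1] + 1, s[1])
                wsl = slice(dw, dw + (wo - 1) * s[2] + 1, s[2])
                buf[:, :, idx] = xp[:, :, dsl, hsl, wsl]
                idx += 1
    return buf.reshape(n, cin * kk, dlen * ho * wo)


def _slab_size(xp, k, dims):
    n, cin = xp.shape[:2]
    per_depth = n * cin * int(np.prod(k)) * dims[1] * dims[2]
    return max(1, _CONV_BUDGET // per_depth)


def _conv_corr(xp, w, s):
    """Cross-correlation of padded ``xp`` [N,Cin,...] with ``w`` [Cout,Cin,k...].

    One GEMM per depth slab over a column buffer whose size stays below a
    fixed budget.  Returns [N, Cout, Do, Ho, Wo].
    """
    n = xp.shape[0]
    cout = w.shape[0]
    k = w.shape[2:]
    dims, _ = _offset_slices(xp.shape, k, s)
    do, ho, wo = dims
    w2 = w.reshape(cout, -1)
    out = np.empty((n, cout, do, ho, wo), dtype=np.float32)
    chunk = _slab_size(xp, k, dims)
    for d0 in range(0, do, chunk):
        d1 = min(do, d0 + chunk)
        buf = _im2col_slab(xp, k, s, dims, d0, d1)
        out[:, :, d0:d1] = np.matmul(w2, buf).reshape(n, cout, d1 - d0, ho, wo)
    return out


def _conv_grad_w(xp, g, k, s):
    """Kernel gradient via the same column buffers; ``g`` is [N,Cout,Do,Ho,Wo]."""
    n, cout = g.shape[:2]
    dims = g.shape[2:]
    gw = None
    chunk = _slab_size(xp, k, dims)
    for d0 in range(0, dims[0], chunk):
        d1 = min(dims[0], d0 + chunk)
        buf = _im2col_slab(xp, k, s, dims, d0, d1)
        g2 = g[:, :, d0:d1].reshape(n, cout, -1)
        part = np.einsum("nov,nkv->ok", g2, buf, optimize=True)
        gw = part if gw is None else gw + part
    return gw.reshape((cout, xp.shape[1]) + tuple(k))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=1) -> Tensor:
    """3-D cross-correlation.

    ``x``: [N, Cin, D, H, W]; ``w``: [Cout, Cin, kd, kh, kw]; zero padding.
    Anisotropic kernels (e.g. 1×3×3) make this double as a 2-D convolution.
    """
    x, w = as_tensor(x), as_tensor(w)
    s, p = _triple(stride), _triple(padding)
    k = w.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0)) + tuple((pi, pi) for pi in p))
    out = _conv_corr(xp, w.data, s)
    if b is not None:
        out += b.data[None, :, None, None, None]

    def back(g):
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad or w._parents:
            w._accum(_conv_grad_w(xp, g, k, s))
        if x.requires_grad or x._parents:
            # dilate by stride, pad to "full", correlate with flipped kernel
            N, Co = g.shape[:2]
            do = [(g.shape[2 + i] - 1) * s[i] + 1 for i in range(3)]
            gd = np.zeros((N, Co, *do), dtype=np.float32)
            gd[:, :, ::s[0], ::s[1], ::s[2]] = g
            pads = []
            for i in range(3):
                left = k[i] - 1 - p[i]
                need = x.shape[2 + i] + k[i] - 1
                right = need - (do[i] + left)
                pads.append((left, right))
            gp = np.pad(gd, ((0, 0), (0, 0)) + tuple(pads))
            wf = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            x._accum(_conv_corr(gp, wf, (1, 1, 1)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, back)


def maxpool3d(x: Tensor) -> Tensor:
    """2×2×2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d needs even spatial dims, got {(D, H, W)}")
    win = x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    data = win.max(axis=(3, 5, 7))

    def back(g):
        m = data[:, :, :, None, :, None, :, None]
        mask = (win == m).astype(np.float32)
        mask /= mask.sum(axis=(3, 5, 7), keepdims=True)
        gx = mask * g[:, :, :, None, :, None, :, None]
        x._accum(gx.reshape(N, C, D, H, W))

    return _make(data, (x,), back)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean, var,
               eps: float = 1e-5, batch_stats: bool = False) -> Tensor:
    """Normalize [N, C, D, H, W] features per channel with given statistics.

    ``mean``/``var`` are arrays of shape [C].  With ``batch_stats=True``
    they are the statistics of ``x`` itself and their dependence on ``x``
    is differentiated analytically; otherwise (inference with running
    statistics) they are constants.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    sh = (1, -1, 1, 1, 1)
    mu = np.asarray(mean, dtype=np.float32).reshape(sh)
    inv = (1.0 / np.sqrt(np.asarray(var, dtype=np.float32) + eps)).reshape(sh)
    xhat = (x.data - mu) * inv
    data = gamma.data.reshape(sh) * xhat + beta.data.reshape(sh)

    def back(g):
        axes = (0, 2, 3, 4)
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad or x._parents:
            gi = gamma.data.reshape(sh) * inv
            if not batch_stats:
                x._accum(g * gi)
            else:
                m = g.size // g.shape[1]
                gsum = g.sum(axis=axes, keepdims=True)
                gxsum = (g * xhat).sum(axis=axes, keepdims=True)
                x._accum(gi / m * (m * g - gsum - xhat * gxsum))

    return _make(data, (x, gamma, beta), back)


def _interp_axis(n_in, n_out):
    """1-D linear interpolation weights (half-pixel centers, clipped)."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    wt = (src - lo).astype(np.float32)
    return lo, hi, wt


def upsample_linear3d(x: Tensor, scale=2) -> Tensor:
    """Linear-interpolation resampling of the three spatial axes."""
    x = as_tensor(x)
    plans = []
    data = x.data
    for ax in (2, 3, 4):
        n_in = data.shape[ax]
        lo, hi, wt = _interp_axis(n_in, n_in * scale)
        sh = [1] * data.ndim
        sh[ax] = len(wt)
        wb = wt.reshape(sh)
        data = np.take(data, lo, axis=ax) * (1 - wb) + np.take(data, hi, axis=ax) * wb
        plans.append((ax, n_in, lo, hi, wb))

    def back(g):
        for ax, n_in, lo, hi, wb in reversed(plans):
            shape = list(g.shape)
            shape[ax] = n_in
            gx = np.zeros(shape, dtype=np.float32)
            gm = np.moveaxis(gx, ax, 0)
            glo = np.moveaxis(g * (1 - wb), ax, 0)
            ghi = np.moveaxis(g * wb, ax, 0)
            np.add.at(gm, lo, glo)
            np.add.at(gm, hi, ghi)
            g = gx
        x._accum(g)

    return _make(data, (x,), back)
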