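"""Minimal layer/module system on top of the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d, linear, relu, sigmoid

__all__ = ["Module", "Conv3d", "Conv2d", "BatchNorm3d", "Linear", "Dropout",
           "Sequential", "ReLU", "Sigmoid"]


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name, array):
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name, array):
        arr = np.asarray(array, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def named_buffers(self, prefix=""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self, frozen=True):
        for p in self.parameters():
            p.requires_grad = not frozen
        return self

    def state_dict(self):
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float32).copy()
        for n, b in self.named_buffers():
            b[...] = state["buf:" + n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel if isinstance(kernel, tuple) else (kernel,) * 3
        fan_in = in_ch * int(np.prod(k))
        self.register_parameter("weight", _he_init(rng, (out_ch, in_ch, *k), fan_in))
        self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv3d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Conv2d(Module):
    """2-D convolution on [N, C, A, B] maps, run as a 1×k×k 3-D conv."""

    def __init__(self, in_ch, out_ch, kernel=3, padding=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.register_parameter(
            "weight", _he_init(rng, (out_ch, in_ch, 1, kernel, kernel), fan_in))
        self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))
        self.padding = padding

    def forward(self, x):
        from .tensor import reshape
        n, c, a, b = x.shape
        x5 = reshape(x, (n, c, 1, a, b))
        y = conv3d(x5, self.weight, self.bias,
                   stride=1, padding=(0, self.padding, self.padding))
        return reshape(y, (y.shape[0], y.shape[1], y.shape[3], y.shape[4]))


class BatchNorm3d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.register_parameter("gamma", np.ones(num_features, dtype=np.float32))
        self.register_parameter("beta", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        from .tensor import batch_norm
        if self.training:
            axes = (0, 2, 3, 4)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return batch_norm(x, self.gamma, self.beta, mu, var, self.eps,
                              batch_stats=True)
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.eps)


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.register_parameter("weight", _he_init(rng, (out_f, in_f), in_f))
        self.register_parameter("bias", np.zeros(out_f, dtype=np.float32))

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Uses its own seeded RNG."""

    def __init__(self, rate=0.5, rng=None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
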