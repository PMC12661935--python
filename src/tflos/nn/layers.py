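"""Neural-network modules over the autograd engine.

Every parameterized module takes an explicit ``numpy.random.Generator`` so
that model construction is deterministic under a seed — the reproducibility
contract for training runs.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, is_grad_enabled

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d", "Linear",
    "SiLU", "ReLU", "Sigmoid",
]


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix=""):
        state = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                state[prefix + k] = v.data.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{prefix}{k}.{i}."))
        return state

    def load_state_dict(self, state, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data[...] = state[prefix + k]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=None, bias=True,
                 rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        fan_in = cin * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (cout, cin, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros(c, np.float32))
        self.running_var = Tensor(np.ones(c, np.float32))

    def forward(self, x):
        gamma, beta = self.gamma, self.beta
        if self.training and is_grad_enabled():
            # fused primitive: batch statistics with hand-written backward
            data = x.data
            axes = (0, 2, 3)
            n = data.shape[0] * data.shape[2] * data.shape[3]
            mu = data.mean(axis=axes, keepdims=True)
            xc = data - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            inv = 1.0 / np.sqrt(var + self.eps)
            xn = xc * inv
            self.running_mean.data[...] = ((1 - self.momentum) * self.running_mean.data
                                           + self.momentum * mu.ravel())
            self.running_var.data[...] = ((1 - self.momentum) * self.running_var.data
                                          + self.momentum * var.ravel())
            out_data = xn * gamma.data.reshape(1, -1, 1, 1) \
                + beta.data.reshape(1, -1, 1, 1)

            def bw(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xn).sum(axis=axes))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=axes))
                if x.requires_grad:
                    gm = g.mean(axis=axes, keepdims=True)
                    gxn = (g * xn).mean(axis=axes, keepdims=True)
                    coeff = gamma.data.reshape(1, -1, 1, 1) * inv
                    x._accumulate(coeff * (g - gm - xn * gxn))

            return Tensor._make(out_data, (x, gamma, beta), bw)
        mu = self.running_mean.data.reshape(1, -1, 1, 1)
        sd = np.sqrt(self.running_var.data + self.eps).reshape(1, -1, 1, 1)
        xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / cin)
        self.weight = Tensor(rng.uniform(-bound, bound, (cin, cout)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
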