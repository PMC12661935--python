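"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps a float32 ndarray and
remembers how to push gradients to its parents.  It supports exactly the
operations the detector and the stage classifier need — elementwise
arithmetic, matmul, im2col convolution, pooling, nearest upsampling,
bilinear sampling, reductions, slicing/concatenation and the usual
nonlinearities — nothing more.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _to_float(data) -> np.ndarray:
    """float32 by default; float64 inputs are preserved (gradient checks)."""
    arr = np.asarray(data)
    if arr.dtype == np.float64:
        return arr
    if arr.dtype != np.float32:
        return arr.astype(np.float32)
    return arr


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _to_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- graph-node construction ------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        mask = self.data == (out_data if keepdims or axis is None
                             else np.expand_dims(out_data, axis))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            nmax = mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask * g / nmax)

        return Tensor._make(out_data, (self,), bw)

    # -- nonlinearities ----------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accumulate(g * (self.data > 0))

        return Tensor._make(out_data, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accumulate(g * e)

        return Tensor._make(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / np.maximum(r, 1e-12))

        return Tensor._make(r, (self,), bw)

    def arctan(self):
        def bw(g):
            self._accumulate(g / (1.0 + self.data ** 2))

        return Tensor._make(np.arctan(self.data), (self,), bw)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.minimum(self.data, other.data)
        mask = self.data <= other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.maximum(self.data, other.data)
        mask = self.data >= other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return Tensor._make(s, (self,), bw)

    # -- structured ops ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride: int = 1, padding: int = 0):
        """2-D cross-correlation via im2col + GEMM.

        x: (B, Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,) or None.
        """
        x = self.data
        w = weight.data
        B, Cin, H, W = x.shape
        Cout, _, kh, kw = w.shape
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        Ho = (xp.shape[2] - kh) // stride + 1
        Wo = (xp.shape[3] - kw) // stride + 1
        # (B, Cin, kh, kw, Ho, Wo)
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]          # (B, Cin, Ho, Wo, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, Cin * kh * kw)
        cols = np.ascontiguousarray(cols)
        wmat = w.reshape(Cout, -1)
        out = cols @ wmat.T                           # (B*Ho*Wo, Cout)
        if bias is not None:
            out = out + bias.data
        out_data = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

        def bw(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Cout)
            if weight.requires_grad:
                weight._accumulate((gmat.T @ cols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gmat.sum(axis=0))
            if self.requires_grad:
                gcols = gmat @ wmat                   # (B*Ho*Wo, Cin*kh*kw)
                gcols = gcols.reshape(B, Ho, Wo, Cin, kh, kw)
                gx = np.zeros_like(xp)
                # col2im scatter-add
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accumulate(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def maxpool2d(self, kernel: int, stride: int = None, padding: int = 0):
        stride = stride or kernel
        x = self.data
        B, C, H, W = x.shape
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                        constant_values=-np.inf)
        else:
            xp = x
        Ho = (xp.shape[2] - kernel) // stride + 1
        Wo = (xp.shape[3] - kernel) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
        win = win[:, :, ::stride, ::stride].reshape(B, C, Ho, Wo, kernel * kernel)
        arg = win.argmax(axis=-1)
        out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gx = np.zeros_like(xp)
            ki, kj = np.divmod(arg, kernel)
            bi, ci, hi, wi = np.meshgrid(np.arange(B), np.arange(C), np.arange(Ho),
                                         np.arange(Wo), indexing="ij")
            np.add.at(gx, (bi, ci, hi * stride + ki, wi * stride + kj), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bw)

    def upsample_nearest(self, scale: int = 2):
        out_data = self.data.repeat(scale, axis=2).repeat(scale, axis=3)

        def bw(g):
            B, C, H, W = self.data.shape
            self._accumulate(
                g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            )

        return Tensor._make(out_data, (self,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)
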