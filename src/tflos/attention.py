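"""Channel and spatial attention blocks used inside the detector.

Three mechanisms live here:

* **SE (Squeeze-and-Excitation)** — global average pooling per channel
  followed by a two-layer bottleneck and a sigmoid gate that rescales each
  channel.
* **Coordinate Attention (CA)** — global pooling factorized into two 1-D
  directions, z^h_c(h) = (1/W) Σ_i x_c(h, i) and z^w_c(w) = (1/H) Σ_j
  x_c(j, w); the encoded descriptors yield one attention profile per spatial
  direction and the input is reweighted by their outer product.
* **AFT (Attention Free Transformer)** — replaces dot-product attention by
  elementwise gating: Y = σ_q(Q') ⊙ Pool_T(σ_k(K') ⊙ V'), with σ_q a
  sigmoid output gate, σ_k a softmax over the sequence axis and Pool a sum.
  No T×T attention matrix is ever materialized.

``CAAFT`` composes them: CA reweights the map, the spatial positions are
flattened to a sequence of length H·W, AFT mixes them, and the map shape is
restored.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# Squeeze-and-Excitation
# ---------------------------------------------------------------------------

class SELayer(nn.Module):
    """Channel gate: x_c -> x_c * sigmoid(W2 relu(W1 squeeze(x))_c).

    reduction_ratio defaults to 16, the convention of the mechanism; the
    bottleneck width is max(1, C // reduction_ratio).
    """

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 rng: np.random.Generator = None):
        super().__init__()
        if reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction_ratio)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        """Per-channel gate vector, shape (B, C); every entry in (0, 1)."""
        squeeze = x.mean(axis=(2, 3))           # (B, C) global pooling
        return self.fc2(self.fc1(squeeze).relu()).sigmoid()

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ValueError(f"expected (B,{self.channels},H,W), got {x.shape}")
        g = self.gates(x)
        B, C = g.shape
        return x * g.reshape(B, C, 1, 1)


def se_forward(x, layer: SELayer) -> Tensor:
    """Functional alias for :meth:`SELayer.forward`."""
    return layer(x)


# ---------------------------------------------------------------------------
# Coordinate Attention
# ---------------------------------------------------------------------------

def ca_pool(x):
    """Direction-aware 1-D pooling.

    Returns ``(z_h, z_w)`` with shapes (B, C, H, 1) and (B, C, 1, W):
    z_h averages over the width axis with factor 1/W, z_w over the height
    axis with factor 1/H.
    """
    x = _as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected rank-4 input, got {x.shape}")
    z_h = x.mean(axis=3, keepdims=True)   # (B, C, H, 1)
    z_w = x.mean(axis=2, keepdims=True)   # (B, C, 1, W)
    return z_h, z_w


def ca_reweight(x, a_h, a_w) -> Tensor:
    """Reweight by two 1-D attention profiles.

    out(b,c,h,w) = x(b,c,h,w) * a_h(b,c,h) * a_w(b,c,w); a_h has shape
    (B, C, H, 1) and a_w (B, C, 1, W) so the product broadcasts.
    """
    x, a_h, a_w = _as_tensor(x), _as_tensor(a_h), _as_tensor(a_w)
    B, C, H, W = x.shape
    if a_h.shape != (B, C, H, 1) or a_w.shape != (B, C, 1, W):
        raise ValueError(
            f"descriptor shapes {a_h.shape}, {a_w.shape} do not match input {x.shape}")
    return x * a_h * a_w


class CoordAtt(nn.Module):
    """Full CA block: pool -> shared 1x1 encoding -> split -> sigmoid -> reweight."""

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction_ratio)
        self.conv1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.act = nn.SiLU()
        self.conv_h = nn.Conv2d(hidden, channels, 1, rng=rng)
        self.conv_w = nn.Conv2d(hidden, channels, 1, rng=rng)

    def attentions(self, x: Tensor):
        z_h, z_w = ca_pool(x)
        B, C, H, _ = z_h.shape
        W = z_w.shape[3]
        # concatenate along the spatial dimension: (B, C, H+W, 1)
        y = nn.concat([z_h, z_w.transpose(0, 1, 3, 2)], axis=2)
        y = self.act(self.conv1(y))
        y_h = y[:, :, :H, :]
        y_w = y[:, :, H:, :].transpose(0, 1, 3, 2)
        a_h = self.conv_h(y_h).sigmoid()          # (B, C, H, 1)
        a_w = self.conv_w(y_w).sigmoid()          # (B, C, 1, W)
        return a_h, a_w

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        a_h, a_w = self.attentions(x)
        return ca_reweight(x, a_h, a_w)


# ---------------------------------------------------------------------------
# Attention Free Transformer
# ---------------------------------------------------------------------------

class AFT(nn.Module):
    """Positional-bias-free AFT layer on sequences of shape (B, T, d).

    Y = sigma_q(Q') * Pool_T(sigma_k(K') * V'), Q' = x W_Q etc.  The pooled
    context is a single (B, 1, d) vector, so extra memory is O(T*d).
    """

    def __init__(self, dim: int, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.w_q = nn.Linear(dim, dim, rng=rng)
        self.w_k = nn.Linear(dim, dim, rng=rng)
        self.w_v = nn.Linear(dim, dim, rng=rng)

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        squeeze_batch = x.ndim == 2
        if squeeze_batch:
            x = x.reshape(1, *x.shape)
        if x.shape[-1] != self.dim:
            raise ValueError(f"model dimension {x.shape[-1]} != {self.dim}")
        q = self.w_q(x)
        k = self.w_k(x)
        v = self.w_v(x)
        ctx = (k.softmax(axis=1) * v).sum(axis=1, keepdims=True)  # (B, 1, d)
        y = q.sigmoid() * ctx
        return y.reshape(y.shape[1], y.shape[2]) if squeeze_batch else y


def aft_forward(x_seq, layer: AFT) -> Tensor:
    """Functional alias for :meth:`AFT.forward`."""
    return layer(x_seq)


# ---------------------------------------------------------------------------
# CAAFT
# ---------------------------------------------------------------------------

class CAAFT(nn.Module):
    """Coordinate Attention followed by an AFT over flattened positions.

    The AFT output passes through a sigmoid-gated residual: out = m + aft(m)
    where m is the CA-reweighted map; ``ca_first=False`` swaps the order for
    ablation.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16, ca_first: bool = True,
                 rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.ca_first = ca_first
        self.ca = CoordAtt(channels, reduction_ratio, rng=rng)
        self.aft = AFT(channels, rng=rng)

    def _aft_on_map(self, m: Tensor) -> Tensor:
        B, C, H, W = m.shape
        seq = m.reshape(B, C, H * W).transpose(0, 2, 1)     # (B, T, C)
        y = self.aft(seq)
        y = y.transpose(0, 2, 1).reshape(B, C, H, W)
        return m + y

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        if self.ca_first:
            return self._aft_on_map(self.ca(x))
        return self.ca(self._aft_on_map(x))


def caaft_forward(x, layer: CAAFT) -> Tensor:
    """Functional alias for :meth:`CAAFT.forward`."""
    return layer(x)
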