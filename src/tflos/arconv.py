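"""Adaptive Rectangular Convolution (ARConv).

A convolution whose kernel *extent* is predicted from the input: two small
subnetworks regress per-pixel kernel height and width maps

    h = a1 * sigmoid(f_theta1(x)) + b1,     w = a2 * sigmoid(f_theta2(x)) + b2,

the spatial means h_bar, w_bar are converted to odd integer kernel sizes
k_h, k_w, and each output pixel gathers k_h*k_w samples on a rectangular
grid whose spacing is scaled per pixel by Z0 = (h0/k_h, w0/k_w).  Sampling
positions are generally non-integer, so values are gathered by bilinear
interpolation (zero padding outside the map).  The gathered sampling map S
is convolved with a learned kernel bank SK and modulated elementwise by two
predicted affine maps:  y = SK (*) S .* M (+) B.

Gradients flow to the input, the kernel bank and the affine subnets; the
predicted h/w fields steer the sampling grid through a stop-gradient (the
grid is geometry, not a graph node).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# elementary operations (exposed for testing against loop oracles)
# ---------------------------------------------------------------------------

@dataclass
class HWFields:
    """Predicted per-pixel kernel-extent fields and their spatial means."""
    h_map: np.ndarray       # (B, 1, H, W), entries in (b1, a1+b1)
    w_map: np.ndarray       # (B, 1, H, W), entries in (b2, a2+b2)
    h_bar: float
    w_bar: float


def kernel_size(mean_value: float) -> int:
    """Convert a mean kernel extent to an odd integer size.

    phi(x) = x - [x is even] applied to floor(mean_value); clamped to >= 1.
    """
    if mean_value <= 0:
        raise ValueError(f"mean kernel extent must be positive, got {mean_value}")
    k = int(np.floor(mean_value))
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


def build_offsets(h0: float, w0: float, k_h: int, k_w: int) -> np.ndarray:
    """Offset matrix R = Z0 ⊙ G, shape (k_h*k_w, 2) in (row, col) order.

    G spans the integer offsets -(k-1)/2 .. (k-1)/2 on each axis;
    Z0 = (h0/k_h, w0/k_w) rescales the grid so its footprint is h0 x w0.
    """
    if k_h % 2 == 0 or k_w % 2 == 0 or k_h < 1 or k_w < 1:
        raise ValueError(f"kernel sizes must be odd and >= 1, got {k_h}x{k_w}")
    gi = np.arange(k_h) - (k_h - 1) / 2.0
    gj = np.arange(k_w) - (k_w - 1) / 2.0
    G = np.stack(np.meshgrid(gi, gj, indexing="ij"), axis=-1).reshape(-1, 2)
    Z0 = np.array([h0 / k_h, w0 / k_w])
    return G * Z0


def bilinear_sample(x, positions):
    """Sample a feature map at real-valued positions with zero padding.

    x: Tensor or array (B, C, H, W); positions: array (B, K, H', W', 2) or
    any shape (..., 2) with leading batch axis, in (row, col) pixel
    coordinates.  Returns (B, C, *positions.shape[1:-1]).  Integer positions
    reproduce stored values exactly; contributions from outside the map are
    zero.  Differentiable with respect to x.
    """
    is_tensor = isinstance(x, Tensor)
    xt = x if is_tensor else Tensor(np.asarray(x))
    data = xt.data
    B, C, H, W = data.shape
    pos = np.asarray(positions, dtype=np.float64)
    out_spatial = pos.shape[1:-1]
    P = int(np.prod(out_spatial)) if out_spatial else 1
    p = pos.reshape(B, P, 2)
    r, c = p[..., 0], p[..., 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    dr = (r - r0).astype(data.dtype)
    dc = (c - c0).astype(data.dtype)

    corners = []
    for oi, oj, w_ in ((0, 0, (1 - dr) * (1 - dc)), (0, 1, (1 - dr) * dc),
                       (1, 0, dr * (1 - dc)), (1, 1, dr * dc)):
        ri, ci = r0 + oi, c0 + oj
        valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
        corners.append((np.clip(ri, 0, H - 1), np.clip(ci, 0, W - 1),
                        (w_ * valid).astype(data.dtype)))

    bidx = np.arange(B)[:, None]
    out = np.zeros((B, C, P), dtype=data.dtype)
    for ri, ci, w_ in corners:
        out += data[bidx, :, ri, ci].transpose(0, 2, 1) * w_[:, None, :]

    out = out.reshape(B, C, *out_spatial)

    if not is_tensor or not xt.requires_grad:
        return out if not is_tensor else Tensor._make(out, (xt,), None)

    def bw(g):
        gflat = g.reshape(B, C, P)
        gx = np.zeros_like(data)
        for ri, ci, w_ in corners:
            # scatter-add g * weight into the 4 neighbours
            contrib = gflat * w_[:, None, :]            # (B, C, P)
            bb = np.broadcast_to(bidx[:, None, :], (B, C, P))
            cc = np.broadcast_to(np.arange(C)[None, :, None], (B, C, P))
            rr = np.broadcast_to(ri[:, None, :], (B, C, P))
            cc2 = np.broadcast_to(ci[:, None, :], (B, C, P))
            np.add.at(gx, (bb, cc, rr, cc2), contrib)
        xt._accumulate(gx)

    return Tensor._make(out, (xt,), bw)


# ---------------------------------------------------------------------------
# the layer
# ---------------------------------------------------------------------------

class _HWSubnet(nn.Module):
    """3x3 conv -> BN -> SiLU -> 1x1 conv to a single channel."""

    def __init__(self, cin, width=8, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, width, 3, rng=rng)
        self.bn = nn.BatchNorm2d(width)
        self.act = nn.SiLU()
        self.conv2 = nn.Conv2d(width, 1, 1, rng=rng)

    def forward(self, x):
        return self.conv2(self.act(self.bn(self.conv1(x))))


class ARConv(nn.Module):
    """Adaptive rectangular convolution layer (stride 1, shape preserving).

    Parameters
    ----------
    cin, cout : channel counts.
    a, b : scale/shift applied after the sigmoid, for both axes; kernel
        extents live in the open interval (b, a+b).  Defaults a=6, b=1
        keep the footprint within 1-7 pixels.
    subnet_width : hidden width of the h/w prediction subnets.
    max_kernel : upper bound on k_h, k_w (caps cost when a+b is large).
    """

    def __init__(self, cin, cout, a=(6.0, 6.0), b=(1.0, 1.0), subnet_width=8,
                 max_kernel=7, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if a[0] <= 0 or a[1] <= 0:
            raise ValueError("scale factors a must be positive")
        self.cin, self.cout = cin, cout
        self.a, self.b = tuple(a), tuple(b)
        self.max_kernel = max_kernel
        self.f_h = _HWSubnet(cin, subnet_width, rng=rng)
        self.f_w = _HWSubnet(cin, subnet_width, rng=rng)
        kmax = max(kernel_size(a[0] + b[0]), kernel_size(a[1] + b[1]), 3)
        kmax = min(kmax, max_kernel)
        # one learned kernel bank SK, sliced to (k_h, k_w) per forward pass
        fan_in = cin * kmax * kmax
        self.sk = Tensor(np.random.default_rng(rng.integers(2**31)).normal(
            0, np.sqrt(2.0 / fan_in), (cout, cin, kmax, kmax)).astype(np.float32),
            requires_grad=True)
        self.m_net = nn.Conv2d(cin, cout, 1, rng=rng)
        self.b_net = nn.Conv2d(cin, cout, 1, rng=rng)
        # identity-affine initialisation: M == 1, B == 0 at start
        self.m_net.weight.data[...] = 0.0
        self.m_net.bias.data[...] = 1.0
        self.b_net.weight.data[...] = 0.0
        self.b_net.bias.data[...] = 0.0
        self.use_affine = True

    # -- pieces ------------------------------------------------------------
    def predict_hw(self, x) -> HWFields:
        """Eqs. h = a1*sigmoid(f1(x)) + b1 and w = a2*sigmoid(f2(x)) + b2."""
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        with nn.no_grad():
            h = self.f_h(xt.detach()).sigmoid() * self.a[0] + self.b[0]
            w = self.f_w(xt.detach()).sigmoid() * self.a[1] + self.b[1]
        return HWFields(h.data, w.data, float(h.data.mean()), float(w.data.mean()))

    def _positions(self, hw: HWFields, H: int, W: int, force_hw=None):
        if force_hw is not None:
            h0 = np.full_like(hw.h_map, force_hw[0])
            w0 = np.full_like(hw.w_map, force_hw[1])
            k_h = kernel_size(force_hw[0])
            k_w = kernel_size(force_hw[1])
        else:
            h0, w0 = hw.h_map, hw.w_map
            k_h = min(kernel_size(hw.h_bar), self.max_kernel)
            k_w = min(kernel_size(hw.w_bar), self.max_kernel)
        B = h0.shape[0]
        gi = np.arange(k_h) - (k_h - 1) / 2.0
        gj = np.arange(k_w) - (k_w - 1) / 2.0
        G = np.stack(np.meshgrid(gi, gj, indexing="ij"), axis=-1).reshape(-1, 2)
        # per-pixel offsets R = Z0 .* G : (B, K, H, W, 2)
        z_r = (h0[:, 0] / k_h)[:, None, :, :]
        z_c = (w0[:, 0] / k_w)[:, None, :, :]
        off_r = G[None, :, 0, None, None] * z_r
        off_c = G[None, :, 1, None, None] * z_c
        pr = np.arange(H)[None, None, :, None] + off_r
        pc = np.arange(W)[None, None, None, :] + off_c
        pos = np.stack(np.broadcast_arrays(pr, pc), axis=-1)   # (B, K, H, W, 2)
        return pos, k_h, k_w

    # -- forward -----------------------------------------------------------
    def forward(self, x, force_hw=None):
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        B, C, H, W = xt.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        hw = self.predict_hw(xt)
        pos, k_h, k_w = self._positions(hw, H, W, force_hw=force_hw)
        s = bilinear_sample(xt, pos)                    # (B, C, K, H, W)
        K = k_h * k_w
        # slice the central (k_h, k_w) window of the kernel bank
        kmax = self.sk.shape[2]
        r0 = (kmax - k_h) // 2
        c0 = (kmax - k_w) // 2
        sk = self.sk[:, :, r0:r0 + k_h, c0:c0 + k_w].reshape(self.cout, C * K)
        s2 = s.reshape(B, C * K, H * W).transpose(0, 2, 1)    # (B, HW, C*K)
        y = (s2 @ sk.transpose(1, 0)).transpose(0, 2, 1).reshape(B, self.cout, H, W)
        if self.use_affine:
            y = y * self.m_net(xt) + self.b_net(xt)
        return y
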