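"""TflosYOLO: a CSPDarknet backbone with SE, ARConv and CAAFT enhancements,
a PANet feature-fusion neck and three anchor-based detection heads.

The assembly follows the YOLOv5 lineage: a stride-2 stem, four backbone
stages of Conv + C3 blocks, an SPPF pyramid pool, top-down and bottom-up
fusion paths, and heads at strides 8/16/32 (grids 80/40/20 at a 640-px
input).  The three enhancements are config-switchable:

* an SE channel-attention block after backbone layer 7 (the deep stride-2
  conv), ``use_se``;
* ARConv replacing the 3x3 convolutions inside the C3 bottlenecks of the
  chosen backbone stages, ``arconv_stages`` (stage numbers 1-4);
* a CAAFT block after the backbone (between SPPF and the neck),
  ``use_caaft``.

Raw head outputs carry (n_anchors * (5 + n_classes)) channels: box offsets
(t_x, t_y, t_w, t_h), an objectness logit and per-class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .arconv import ARConv
from .attention import CAAFT, SELayer

#: YOLOv5 COCO anchors (w, h) pixels at 640-px input, one triple per scale
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

STRIDES = (8, 16, 32)


@dataclass
class ModelConfig:
    input_size: int = 640
    n_classes: int = 3
    depth_multiple: float = 0.67          # YOLOv5m
    width_multiple: float = 0.75
    se_layer_index: int = 7
    use_se: bool = True
    arconv_stages: tuple = (2, 3)
    arconv_a: float = 6.0
    arconv_b: float = 1.0
    arconv_subnet_width: int = 8
    use_caaft: bool = True
    caaft_placement: str = "after_backbone"
    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple = STRIDES
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, "
                             f"got {self.input_size}")
        if self.se_layer_index != 7:
            raise ValueError("the SE block is wired after backbone layer 7; "
                             "other placements are not implemented")

    def to_dict(self):
        return {k: (list(map(list, v)) if k == "anchors" else
                    (list(v) if isinstance(v, tuple) else v))
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "anchors" in d:
            d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in d["anchors"])
        for k in ("arconv_stages", "strides"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _width(c, wm):
    return max(8, int(np.ceil(c * wm / 8)) * 8)


def _depth(n, dm):
    return max(1, round(n * dm))


class ConvBNAct(nn.Module):
    def __init__(self, cin, cout, k, s=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=s, padding=(k - 1) // 2,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    def __init__(self, c, shortcut=True, use_arconv=False, arconv_kw=None, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 1, rng=rng)
        if use_arconv:
            self.cv2 = ARConv(c, c, rng=rng, **(arconv_kw or {}))
            self.post = nn.Sequential(nn.BatchNorm2d(c), nn.SiLU())
        else:
            self.cv2 = ConvBNAct(c, c, 3, rng=rng)
            self.post = nn.Identity()
        self.shortcut = shortcut

    def forward(self, x):
        y = self.post(self.cv2(self.cv1(x)))
        return x + y if self.shortcut else y


class C3(nn.Module):
    def __init__(self, cin, cout, n=1, shortcut=True, use_arconv=False,
                 arconv_kw=None, rng=None):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBNAct(cin, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, c_, 1, rng=rng)
        self.m = [Bottleneck(c_, shortcut, use_arconv, arconv_kw, rng=rng)
                  for _ in range(n)]
        self.cv3 = ConvBNAct(2 * c_, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


class SPPF(nn.Module):
    def __init__(self, cin, cout, k=5, rng=None):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBNAct(cin, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(4 * c_, cout, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = self.cv1(x)
        p1 = y.maxpool2d(self.k, 1, self.k // 2)
        p2 = p1.maxpool2d(self.k, 1, self.k // 2)
        p3 = p2.maxpool2d(self.k, 1, self.k // 2)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))


class Upsample(nn.Module):
    def forward(self, x):
        return x.upsample_nearest(2)


class TflosYOLO(nn.Module):
    """Detector network; ``forward`` returns raw maps for the three scales."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        wm, dm = cfg.width_multiple, cfg.depth_multiple
        c1, c2, c3c, c4, c5 = (_width(c, wm) for c in (64, 128, 256, 512, 1024))
        n1, n2, n3 = _depth(3, dm), _depth(6, dm), _depth(9, dm)
        ar = set(cfg.arconv_stages)
        ar_kw = {"a": (cfg.arconv_a, cfg.arconv_a),
                 "b": (cfg.arconv_b, cfg.arconv_b),
                 "subnet_width": cfg.arconv_subnet_width}

        def c3(cin, cout, n, stage, shortcut=True):
            return C3(cin, cout, n, shortcut,
                      use_arconv=stage in ar, arconv_kw=ar_kw, rng=rng)

        # backbone (layer indices follow the YOLOv5 yaml)
        self.b0 = ConvBNAct(3, c1, 6, 2, rng=rng)
        self.b1 = ConvBNAct(c1, c2, 3, 2, rng=rng)
        self.b2 = c3(c2, c2, n1, stage=1)
        self.b3 = ConvBNAct(c2, c3c, 3, 2, rng=rng)
        self.b4 = c3(c3c, c3c, n2, stage=2)
        self.b5 = ConvBNAct(c3c, c4, 3, 2, rng=rng)
        self.b6 = c3(c4, c4, n3, stage=3)
        self.b7 = ConvBNAct(c4, c5, 3, 2, rng=rng)
        self.se = SELayer(c5, rng=rng) if cfg.use_se else nn.Identity()
        self.b8 = c3(c5, c5, n1, stage=4)
        self.b9 = SPPF(c5, c5, rng=rng)
        self.caaft = CAAFT(c5, rng=rng) if cfg.use_caaft else nn.Identity()

        # neck
        self.n10 = ConvBNAct(c5, c4, 1, rng=rng)
        self.up = Upsample()
        self.n13 = C3(2 * c4, c4, n1, shortcut=False, rng=rng)
        self.n14 = ConvBNAct(c4, c3c, 1, rng=rng)
        self.n17 = C3(2 * c3c, c3c, n1, shortcut=False, rng=rng)
        self.n18 = ConvBNAct(c3c, c3c, 3, 2, rng=rng)
        self.n20 = C3(2 * c3c, c4, n1, shortcut=False, rng=rng)
        self.n21 = ConvBNAct(c4, c4, 3, 2, rng=rng)
        self.n23 = C3(2 * c4, c5, n1, shortcut=False, rng=rng)

        # heads
        na, nc = 3, cfg.n_classes
        self.no = 5 + nc
        self.na = na
        self.heads = [nn.Conv2d(c, na * self.no, 1, rng=rng)
                      for c in (c3c, c4, c5)]
        self._init_head_biases()

    def _init_head_biases(self):
        """Prior-aware bias init: rare-object objectness, class priors."""
        for head, stride in zip(self.heads, self.cfg.strides):
            b = head.bias.data.reshape(self.na, self.no)
            b[:, 4] = np.log(8.0 / (self.cfg.input_size / stride) ** 2)
            b[:, 5:] = np.log(0.6 / (self.cfg.n_classes - 0.99))
            head.bias.data[...] = b.reshape(-1)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        y = self.b1(self.b0(x))
        y = self.b2(y)
        y = self.b4(self.b3(y))
        p3 = y                                    # stride 8 feature
        y = self.b6(self.b5(y))
        p4 = y                                    # stride 16 feature
        y = self.se(self.b7(y))
        y = self.b9(self.b8(y))
        y = self.caaft(y)                         # stride 32 feature

        t10 = self.n10(y)
        y = self.n13(nn.concat([self.up(t10), p4], axis=1))
        t14 = self.n14(y)
        y17 = self.n17(nn.concat([self.up(t14), p3], axis=1))
        y20 = self.n20(nn.concat([self.n18(y17), t14], axis=1))
        y23 = self.n23(nn.concat([self.n21(y20), t10], axis=1))

        return [h(f) for h, f in zip(self.heads, (y17, y20, y23))]


def build_model(cfg: ModelConfig) -> TflosYOLO:
    """Construct a detector from a config (deterministic under cfg.seed)."""
    return TflosYOLO(cfg)


def decode_head(raw, anchors, stride, n_classes):
    """Decode one raw head map (numpy, no grad) to absolute-pixel boxes.

    Returns (boxes_xyxy (N,4), obj (N,), cls_prob (N,nc)) flattened over
    anchors and grid cells.
    """
    arr = raw.data if isinstance(raw, Tensor) else np.asarray(raw)
    B, ch, H, W = arr.shape
    na = len(anchors)
    no = ch // na
    a = arr.reshape(B, na, no, H, W)
    sig = 1.0 / (1.0 + np.exp(-a))
    gx, gy = np.meshgrid(np.arange(W), np.arange(H))
    cx = (sig[:, :, 0] * 2 - 0.5 + gx) * stride
    cy = (sig[:, :, 1] * 2 - 0.5 + gy) * stride
    anc = np.asarray(anchors, np.float64)
    w = (sig[:, :, 2] * 2) ** 2 * anc[None, :, 0, None, None]
    h = (sig[:, :, 3] * 2) ** 2 * anc[None, :, 1, None, None]
    obj = sig[:, :, 4]
    cls = sig[:, :, 5:5 + n_classes]
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=2)
    boxes = boxes.transpose(0, 1, 3, 4, 2).reshape(B, -1, 4)
    obj = obj.reshape(B, -1)
    cls = cls.transpose(0, 1, 3, 4, 2).reshape(B, -1, n_classes)
    return boxes, obj, cls


def kmeans_anchors(wh_pixels: np.ndarray, n_anchors: int = 9, seed: int = 0):
    """Re-estimate anchors from (N, 2) label widths/heights in pixels.

    Plain k-means on (w, h); clusters sorted by area and grouped three per
    scale.  Falls back to quantile-spread anchors when labels are too few.
    """
    from scipy.cluster.vq import kmeans2

    wh = np.asarray(wh_pixels, dtype=np.float64)
    if len(wh) < n_anchors:
        qs = np.linspace(0.1, 0.9, n_anchors)
        sizes = np.quantile(wh.prod(axis=1) ** 0.5, qs) if len(wh) else \
            np.linspace(8, 64, n_anchors)
        centers = np.stack([sizes, sizes], axis=1)
    else:
        centers, _ = kmeans2(wh, n_anchors, minit="++",
                             seed=seed, iter=50)
        centers = centers[np.argsort(centers.prod(axis=1))]
    centers = np.maximum(centers, 2.0)
    return tuple(tuple((float(w), float(h)) for w, h in centers[i:i + 3])
                 for i in range(0, n_anchors, 3))
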