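"""Detector training loss: weighted sum of box, objectness and class terms.

Loss = w_box * l_box + w_obj * l_obj + w_cls * l_cls with defaults
(0.05, 1.0, 0.5).  l_box is 1 - CIoU on matched anchor/cell predictions,
l_obj is binary cross-entropy of objectness against the matched IoU, and
l_cls binary cross-entropy of per-class logits against one-hot targets.
Anchor assignment follows the YOLOv5 rule: a ground truth is assigned to
every anchor whose w/h ratio to the box is within a factor of 4, in its
center cell and the two nearest neighbor cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, concat

BOX_WEIGHT, OBJ_WEIGHT, CLS_WEIGHT = 0.05, 1.0, 0.5
ANCHOR_RATIO_THRESHOLD = 4.0


@dataclass
class LossTerms:
    """The three raw loss components and their weights."""
    l_box: float
    l_obj: float
    l_cls: float
    w_box: float = BOX_WEIGHT
    w_obj: float = OBJ_WEIGHT
    w_cls: float = CLS_WEIGHT

    def __post_init__(self):
        if min(self.w_box, self.w_obj, self.w_cls) < 0:
            raise ValueError("loss weights must be non-negative")


def total_loss(t: LossTerms) -> float:
    """Weighted sum; zero iff every weighted term vanishes."""
    return t.w_box * t.l_box + t.w_obj * t.l_obj + t.w_cls * t.l_cls


def bce_with_logits(x: Tensor, target: np.ndarray, weight=None) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable primitive).

    ``weight`` is an optional elementwise multiplier on the per-element
    loss (used for class-frequency weighting).
    """
    target = np.asarray(target, dtype=x.data.dtype)
    z = x.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * target
    w = np.ones_like(z) if weight is None else \
        np.broadcast_to(np.asarray(weight, z.dtype), z.shape)
    val = (loss * w).mean()
    n = z.size

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        x._accumulate(g * w * (s - target) / n)

    return Tensor._make(np.asarray(val, dtype=z.dtype), (x,), bw)


def ciou(pred_xywh, target_xywh: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted (Tensor (M,4) center format) and
    target boxes (ndarray (M,4)), in any common unit."""
    t = np.asarray(target_xywh, dtype=np.float64)
    px, py, pw, ph = (pred_xywh[:, i] for i in range(4))
    tx, ty, tw, th = (t[:, i] for i in range(4))

    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5

    iw = p_x2.minimum(t_x2) - p_x1.maximum(t_x1)
    ih = p_y2.minimum(t_y2) - p_y1.maximum(t_y1)
    inter = iw.clamp(lo=0) * ih.clamp(lo=0)
    union = pw * ph + tw * th - inter + eps
    iou = inter / union

    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    ch = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4.0 / np.pi ** 2) * ((pw / ph.clamp(lo=eps)).arctan()
                              - Tensor(np.arctan(tw / np.maximum(th, eps)))) ** 2
    with np.errstate(all="ignore"):
        alpha = v.data / np.maximum(1.0 - iou.data + v.data, eps)  # detached
    return iou - rho2 / c2 - Tensor(alpha) * v


def build_targets(targets: np.ndarray, anchors, strides, input_size: int,
                  grid_sizes) -> list:
    """Assign ground truths to (image, anchor, cell) slots per scale.

    ``targets``: (M, 6) rows (image_idx, class, cx, cy, w, h) normalized.
    Returns per scale a dict with index arrays b/a/gj/gi, target boxes in
    grid units relative to the cell origin, and target classes.
    """
    out = []
    targets = np.asarray(targets, dtype=np.float64).reshape(-1, 6)
    for si, (anc, stride, gs) in enumerate(zip(anchors, strides, grid_sizes)):
        anc_g = np.asarray(anc, np.float64) / stride          # grid units
        if len(targets) == 0:
            out.append(dict(b=np.zeros(0, int), a=np.zeros(0, int),
                            gj=np.zeros(0, int), gi=np.zeros(0, int),
                            tbox=np.zeros((0, 4)), tcls=np.zeros(0, int),
                            anchors=anc_g))
            continue
        g_h, g_w = gs
        gxy = targets[:, 2:4] * (g_w, g_h)
        gwh = targets[:, 4:6] * (g_w, g_h)
        # anchor-ratio filter
        r = gwh[:, None, :] / anc_g[None, :, :]
        keep = np.maximum(r, 1 / r).max(axis=2) < ANCHOR_RATIO_THRESHOLD
        ti, ai = np.nonzero(keep)
        if len(ti) == 0:
            out.append(dict(b=np.zeros(0, int), a=np.zeros(0, int),
                            gj=np.zeros(0, int), gi=np.zeros(0, int),
                            tbox=np.zeros((0, 4)), tcls=np.zeros(0, int),
                            anchors=anc_g))
            continue
        bs, as_, gjs, gis, tb, tc = [], [], [], [], [], []
        for t_idx, a_idx in zip(ti, ai):
            gx, gy = gxy[t_idx]
            cells = [(int(gx), int(gy))]
            fx, fy = gx - int(gx), gy - int(gy)
            if fx < 0.5 and gx > 1:
                cells.append((int(gx) - 1, int(gy)))
            elif fx >= 0.5 and gx < g_w - 1:
                cells.append((int(gx) + 1, int(gy)))
            if fy < 0.5 and gy > 1:
                cells.append((int(gx), int(gy) - 1))
            elif fy >= 0.5 and gy < g_h - 1:
                cells.append((int(gx), int(gy) + 1))
            for ci, cj in cells:
                ci = min(max(ci, 0), g_w - 1)
                cj = min(max(cj, 0), g_h - 1)
                bs.append(int(targets[t_idx, 0]))
                as_.append(int(a_idx))
                gis.append(ci)
                gjs.append(cj)
                tb.append([gx - ci, gy - cj, gwh[t_idx, 0], gwh[t_idx, 1]])
                tc.append(int(targets[t_idx, 1]))
        out.append(dict(b=np.array(bs), a=np.array(as_), gj=np.array(gjs),
                        gi=np.array(gis), tbox=np.array(tb),
                        tcls=np.array(tc), anchors=anc_g))
    return out


def compute_loss(preds, targets: np.ndarray, cfg, class_weights=None,
                 obj_target: str = "iou"):
    """Total training loss for one batch.

    ``preds``: raw head Tensors; ``targets``: (M, 6) normalized ground
    truths; ``cfg``: ModelConfig.  ``obj_target`` selects the objectness
    regression target at assigned cells: the matched box IoU (``"iou"``,
    confidence-calibrating) or a constant 1 (``"one"``, faster to converge
    on short schedules).  Returns (loss Tensor, LossTerms).
    """
    nc = cfg.n_classes
    na = 3
    grid_sizes = [(p.shape[2], p.shape[3]) for p in preds]
    assigns = build_targets(targets, cfg.anchors, cfg.strides,
                            cfg.input_size, grid_sizes)
    l_box = Tensor(0.0)
    l_cls = Tensor(0.0)
    l_obj = Tensor(0.0)
    balance = (4.0, 1.0, 0.4)          # per-scale objectness balance
    n_box_terms = 0
    for p, asg, bal in zip(preds, assigns, balance):
        B, ch, H, W = p.shape
        pr = p.reshape(B, na, ch // na, H, W)
        tobj = np.zeros((B, na, H, W), dtype=np.float32)
        if len(asg["b"]):
            ps = pr[asg["b"], asg["a"], :, asg["gj"], asg["gi"]]   # (M, no)
            sig_xy = ps[:, 0:2].sigmoid()
            pxy = sig_xy * 2.0 - 0.5
            anc = asg["anchors"][asg["a"]]                          # (M, 2)
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(anc)
            pbox = concat([pxy, pwh], axis=1)
            iou_t = ciou(pbox, asg["tbox"])
            l_box = l_box + (1.0 - iou_t).mean()
            n_box_terms += 1
            tobj[asg["b"], asg["a"], asg["gj"], asg["gi"]] = 1.0 \
                if obj_target == "one" else \
                np.clip(iou_t.data, 0, None).astype(np.float32)
            if nc > 1:
                t_cls = np.zeros((len(asg["tcls"]), nc), np.float32)
                t_cls[np.arange(len(asg["tcls"])), asg["tcls"]] = 1.0
                l_cls = l_cls + bce_with_logits(ps[:, 5:5 + nc], t_cls,
                                                weight=class_weights)
        l_obj = l_obj + bce_with_logits(pr[:, :, 4], tobj) * bal
    if n_box_terms:
        l_box = l_box * (1.0 / n_box_terms)
        l_cls = l_cls * (1.0 / n_box_terms)
    terms = LossTerms(float(l_box.data), float(l_obj.data), float(l_cls.data))
    loss = l_box * BOX_WEIGHT + l_obj * OBJ_WEIGHT + l_cls * CLS_WEIGHT
    return loss, terms
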