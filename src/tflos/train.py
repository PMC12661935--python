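"""Detector training loop, checkpointing and dataset-level evaluation.

Defaults mirror a full-scale training recipe (300 epochs, batch size 8,
learning rate 0.01, SGD); every knob is overridable for desk-scale runs.
Training is deterministic under a fixed seed (single-process loading, no
nondeterministic kernels).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn.optim import SGD, Adam
from .augment import hsv_jitter, mosaic, rotate
from .detect import detect_image
from .loss import compute_loss
from .metrics import evaluate_detections, r_squared
from .model import ModelConfig, build_model, kmeans_anchors
from .yolo_io import list_split, read_image, read_labels

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 8
    lr: float = 0.01
    optimizer: str = "sgd"          # "sgd" | "adam"
    momentum: float = 0.937
    weight_decay: float = 0.0
    seed: int = 0
    augment: bool = False
    rotation_deg: float = 0.0
    mosaic_prob: float = 0.0
    anchor_mode: str = "default"    # "default" | "kmeans"
    class_weighted_cls: bool = False
    cosine_lr: bool = False
    obj_target: str = "iou"
    ema_decay: float = 0.0          # 0 disables weight averaging
    flip_prob: float = 0.5          # random horizontal flip


def load_split(data_dir, split, input_size):
    """Load one split fully into memory: (images NCHW float, targets)."""
    pairs = list_split(data_dir, split)
    imgs, targets = [], []
    for i, (img_path, lbl_path) in enumerate(pairs):
        img = read_image(img_path)
        if img.shape[0] != input_size or img.shape[1] != input_size:
            from PIL import Image
            img = np.asarray(Image.fromarray(img).resize(
                (input_size, input_size), Image.BILINEAR))
        imgs.append(img)
        labels = read_labels(lbl_path) if lbl_path.exists() else []
        targets.append([(cls, cx, cy, w, h) for cls, cx, cy, w, h in labels])
    return imgs, targets


def _targets_array(batch_targets):
    rows = []
    for bi, labels in enumerate(batch_targets):
        for cls, cx, cy, w, h in labels:
            rows.append((bi, cls, cx, cy, w, h))
    return np.asarray(rows, np.float64).reshape(-1, 6)


def train(model_cfg: ModelConfig, data_dir, train_cfg: TrainConfig,
          checkpoint_path=None):
    """Train a detector on a YOLO-layout dataset directory.

    Returns (model, history); history holds per-epoch train/val loss.
    """
    rng = np.random.Generator(np.random.PCG64(train_cfg.seed))
    imgs, targets = load_split(data_dir, "train", model_cfg.input_size)
    if not imgs:
        raise ValueError(f"empty training split in {data_dir}")
    val_imgs, val_targets = load_split(data_dir, "val", model_cfg.input_size)

    if train_cfg.anchor_mode == "kmeans":
        wh = np.array([(w * model_cfg.input_size, h * model_cfg.input_size)
                       for labels in targets for (_, _, _, w, h) in labels])
        model_cfg.anchors = kmeans_anchors(wh, seed=train_cfg.seed)
        log.info("k-means anchors: %s", model_cfg.anchors)

    class_weights = None
    if train_cfg.class_weighted_cls:
        counts = np.zeros(model_cfg.n_classes)
        for labels in targets:
            for cls, *_ in labels:
                counts[int(cls)] += 1
        inv = counts.sum() / np.maximum(counts, 1)
        class_weights = (inv / inv.mean()).astype(np.float32)

    model = build_model(model_cfg)
    params = model.parameters()
    if train_cfg.optimizer == "adam":
        opt = Adam(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    else:
        opt = SGD(params, lr=train_cfg.lr, momentum=train_cfg.momentum,
                  weight_decay=train_cfg.weight_decay)

    n = len(imgs)
    ema = [p.data.copy() for p in params] if train_cfg.ema_decay else None
    ema_updates = 0
    history = []
    for epoch in range(train_cfg.epochs):
        if train_cfg.cosine_lr and train_cfg.epochs > 1:
            opt.lr = train_cfg.lr * 0.5 * (
                1 + np.cos(np.pi * epoch / (train_cfg.epochs - 1)))
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch_imgs, batch_tgts = [], []
            for i in idx:
                img, labels = imgs[i], targets[i]
                if train_cfg.augment:
                    img, labels = _augment(img, labels, imgs, targets,
                                           rng, train_cfg)
                if train_cfg.flip_prob and rng.uniform() < train_cfg.flip_prob:
                    img = img[:, ::-1]
                    labels = [(c, 1.0 - cx, cy, w, h)
                              for c, cx, cy, w, h in labels]
                batch_imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
                batch_tgts.append(labels)
            x = nn.Tensor(np.stack(batch_imgs))
            preds = model(x)
            loss, terms = compute_loss(preds, _targets_array(batch_tgts),
                                       model_cfg, class_weights=class_weights,
                                       obj_target=train_cfg.obj_target)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema_updates += 1
                # ramped decay so early steps are not frozen in
                d = min(train_cfg.ema_decay,
                        (1 + ema_updates) / (10 + ema_updates))
                for shadow, p in zip(ema, params):
                    shadow *= d
                    shadow += (1 - d) * p.data
            losses.append(float(loss.data))
        val_loss = evaluate_loss(model, val_imgs, val_targets, model_cfg,
                                 train_cfg.batch_size) if val_imgs else float("nan")
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_loss": val_loss}
        history.append(entry)
        log.info("epoch %d: train %.4f val %.4f", epoch,
                 entry["train_loss"], val_loss)

    if ema is not None:
        for shadow, p in zip(ema, params):
            p.data[...] = shadow
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, train_cfg)
    return model, history


def _augment(img, labels, imgs, targets, rng, train_cfg):
    if train_cfg.mosaic_prob and rng.uniform() < train_cfg.mosaic_prob:
        others = rng.integers(0, len(imgs), 3)
        img, labels = mosaic([img] + [imgs[j] for j in others],
                             [labels] + [targets[j] for j in others], rng)
    img = hsv_jitter(img, rng)
    if train_cfg.rotation_deg:
        img, labels = rotate(img, labels,
                             rng.uniform(-train_cfg.rotation_deg,
                                         train_cfg.rotation_deg))
    return img, labels


def evaluate_loss(model, imgs, targets, model_cfg, batch_size=8):
    model.eval()
    losses = []
    with nn.no_grad():
        for start in range(0, len(imgs), batch_size):
            batch = imgs[start:start + batch_size]
            x = nn.Tensor(np.stack([im.astype(np.float32).transpose(2, 0, 1) / 255.0
                                    for im in batch]))
            preds = model(x)
            loss, _ = compute_loss(
                preds, _targets_array(targets[start:start + batch_size]),
                model_cfg)
            losses.append(float(loss.data))
    return float(np.mean(losses)) if losses else float("nan")


def calibrate_count_threshold(model, data_dir, split="train",
                              max_images=None, tta: bool = False):
    """Choose the counting confidence threshold on a training split.

    Counting needs an operating point: the same detector that maximizes
    mAP (swept over all confidences) over- or under-counts at any fixed
    threshold until its confidences are calibrated.  This uses quantile
    (count-matching) calibration: the threshold is the confidence of the
    N-th highest detection over the split, where N is the true total
    object count — the unique point at which total predicted count equals
    total true count.  Calibration data only; never the split being
    reported on.  Returns (threshold, r2_on_calibration_split).
    """
    from .metrics import r_squared

    imgs, targets = load_split(data_dir, split, model.cfg.input_size)
    if max_images:
        imgs, targets = imgs[:max_images], targets[:max_images]
    all_dets = [detect_image(model, im, conf_threshold=0.001, tta=tta)
                for im in imgs]
    n_true = sum(len(t) for t in targets)
    confs = np.sort(np.array([d.confidence for dets in all_dets
                              for d in dets]))[::-1]
    if n_true == 0 or len(confs) == 0:
        return 0.25, float("nan")
    t = float(confs[n_true - 1]) if n_true <= len(confs) else float(confs[-1])
    y = [len(tg) for tg in targets]
    yp = [sum(1 for d in dets if d.confidence >= t) for dets in all_dets]
    try:
        r2 = r_squared(y, yp)
    except ValueError:
        r2 = float("nan")
    log.info("calibrated counting threshold %.3f (split %s, R²=%.3f)",
             t, split, r2)
    return t, r2


def evaluate_dataset(model, data_dir, split="val", conf_threshold=0.001,
                     iou_threshold=0.45, count_conf_threshold=0.25,
                     tta: bool = False):
    """mAP metrics plus counting R² of a trained model on one split."""
    from .boxes import xywhn_to_xyxy

    imgs, targets = load_split(data_dir, split, model.cfg.input_size)
    size = model.cfg.input_size
    nc = model.cfg.n_classes
    all_dets, all_truths = [], []
    y_true, y_pred = [], []
    yc_true = [[] for _ in range(nc)]
    yc_pred = [[] for _ in range(nc)]
    for img, labels in zip(imgs, targets):
        dets = detect_image(model, img, conf_threshold=conf_threshold,
                            iou_threshold=iou_threshold, tta=tta)
        all_dets.append(dets)
        truths = [(cls, tuple(xywhn_to_xyxy(np.array([[cx, cy, w, h]]),
                                            size, size)[0]))
                  for cls, cx, cy, w, h in labels]
        all_truths.append(truths)
        y_true.append(len(labels))
        y_pred.append(sum(1 for d in dets
                          if d.confidence >= count_conf_threshold))
        for c in range(nc):
            yc_true[c].append(sum(1 for l in labels if l[0] == c))
            yc_pred[c].append(sum(1 for d in dets if d.class_id == c
                                  and d.confidence >= count_conf_threshold))
    report = evaluate_detections(all_dets, all_truths,
                                 n_classes=nc,
                                 iou_threshold=0.5,
                                 conf_threshold=count_conf_threshold)

    def _safe_r2(y, yp):
        try:
            return r_squared(y, yp)
        except ValueError:
            return float("nan")

    report["count_r2"] = _safe_r2(y_true, y_pred)
    report["count_r2_per_class"] = [_safe_r2(yc_true[c], yc_pred[c])
                                    for c in range(nc)]
    return report


# ---------------------------------------------------------------------------
# checkpoints (self-describing: config + weights)
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, train_cfg: TrainConfig = None):
    meta = {"model_config": model.cfg.to_dict(),
            "train_config": asdict(train_cfg) if train_cfg else None}
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **{k: v for k, v in state.items()})


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = ModelConfig.from_dict(meta["model_config"])
        model = build_model(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_dict(state)
    return model, meta
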