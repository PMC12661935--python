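"""Tea Flowering Stage Classification (TFSC).

A seven-layer feed-forward network (input, six hidden ReLU layers, softmax
output over the five stages IFS/EFS/MFS/LFS/TFS) mapping per-image flower
counts plus an encoded date to a flowering stage.  The preprocessing
pipeline mirrors a two-year survey design: low-quality accessions are
filtered out, same-accession-same-date records are averaged in groups of
three, year-1 samples are split 8:2 into train/validation and year-2
samples form the test set.

Numerical choices: the time feature is day-of-year / 366 (year-portable);
inputs are z-scored with statistics fitted on the training split only;
hidden widths default to (64, 64, 32, 32, 16, 16); training uses
cross-entropy with Adam at learning rate 1e-3, batch size 16, 80 epochs.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.optim import Adam
from .records import STAGES

log = logging.getLogger(__name__)

HIDDEN_WIDTHS = (64, 64, 32, 32, 16, 16)
MIN_MEDIAN_TOTAL = 3.0      # accession quality rule
GROUP_SIZE = 3


def softmax(o) -> np.ndarray:
    """Stable softmax: shift by the max before exponentiating."""
    o = np.asarray(o, dtype=np.float64)
    z = o - o.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def encode_time(date_str: str) -> float:
    """Day-of-year / 366, a single year-portable real feature."""
    d = dt.date.fromisoformat(str(date_str))
    return d.timetuple().tm_yday / 366.0


@dataclass
class StageSample:
    n_bud: float
    n_bloom: float
    n_wither: float
    time_feature: float
    label: str
    accession: str

    @property
    def features(self):
        return np.array([self.n_bud, self.n_bloom, self.n_wither,
                         self.time_feature], dtype=np.float64)


@dataclass
class StageDataset:
    train: list
    val: list
    test: list


def build_stage_dataset(records, val_fraction: float = 0.2,
                        min_median_total: float = MIN_MEDIAN_TOTAL,
                        seed: int = 0) -> StageDataset:
    """Filter, average-by-threes and split count records into stage samples.

    ``records``: CountRecords with date, accession and stage labels.
    Accessions whose median total count over the season is below
    ``min_median_total`` are removed.  Remaining same-accession-same-date
    records are grouped in threes in input order and averaged (leftover
    groups of 1-2 are dropped, keeping the rule exact); a group without a
    stage label is an error.  First-year samples are split
    (1-val_fraction):val_fraction into train/val; later-year samples form
    the test set.
    """
    by_acc = {}
    for r in records:
        if r.accession is None or r.date is None:
            raise ValueError("records need accession and date for staging")
        by_acc.setdefault(r.accession, []).append(r)

    kept = []
    for acc, recs in by_acc.items():
        med = np.median([r.total for r in recs])
        if med < min_median_total:
            log.info("dropping accession %s (median total %.1f < %.1f)",
                     acc, med, min_median_total)
            continue
        kept.extend(recs)

    groups = {}
    order = []
    for r in kept:
        key = (r.accession, r.date)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(r)

    samples = []
    for key in order:
        recs = groups[key]
        for i in range(0, len(recs) - GROUP_SIZE + 1, GROUP_SIZE):
            chunk = recs[i:i + GROUP_SIZE]
            labels = {r.stage for r in chunk}
            if None in labels:
                raise ValueError(f"group {key} lacks a stage label")
            # majority label; ties by stage order
            label = max(sorted(labels, key=STAGES.index),
                        key=[r.stage for r in chunk].count)
            samples.append(StageSample(
                n_bud=float(np.mean([r.n_bud for r in chunk])),
                n_bloom=float(np.mean([r.n_bloom for r in chunk])),
                n_wither=float(np.mean([r.n_wither for r in chunk])),
                time_feature=encode_time(chunk[0].date),
                label=label, accession=key[0]))

    sample_year = [dt.date.fromisoformat(groups[key][0].date).year
                   for key in order
                   for _ in range(len(groups[key]) // GROUP_SIZE)]
    all_years = sorted(set(sample_year))
    first_year = all_years[0] if all_years else None

    year1 = [s for s, y in zip(samples, sample_year) if y == first_year]
    test = [s for s, y in zip(samples, sample_year) if y != first_year]
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(len(year1))
    n_val = int(round(val_fraction * len(year1)))
    val = [year1[i] for i in perm[:n_val]]
    train = [year1[i] for i in perm[n_val:]]
    return StageDataset(train=train, val=val, test=test)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class TFSCNet(nn.Module):
    """Input -> six hidden ReLU layers -> 5-way softmax."""

    def __init__(self, n_features: int = 4, hidden=HIDDEN_WIDTHS,
                 n_classes: int = 5, seed: int = 0):
        super().__init__()
        if len(hidden) != 6:
            raise ValueError("TFSC uses exactly six hidden layers")
        rng = np.random.default_rng(seed)
        widths = (n_features, *hidden)
        self.layers = [nn.Linear(widths[i], widths[i + 1], rng=rng)
                       for i in range(6)]
        self.out = nn.Linear(widths[-1], n_classes, rng=rng)
        # feature scaling (z-score), fitted on the training split only
        self.mu = Tensor(np.zeros(n_features, np.float32))
        self.sd = Tensor(np.ones(n_features, np.float32))

    def fit_scaler(self, features: np.ndarray):
        self.mu.data[...] = features.mean(axis=0)
        self.sd.data[...] = np.maximum(features.std(axis=0), 1e-8)

    def logits(self, features: np.ndarray) -> Tensor:
        x = Tensor((np.asarray(features, np.float64) - self.mu.data)
                   / self.sd.data)
        for layer in self.layers:
            x = layer(x).relu()
        return self.out(x)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return softmax(self.logits(np.atleast_2d(features)).data)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy primitive."""
    z = logits.data
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    n = len(labels)
    val = -logp[np.arange(n), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    return Tensor._make(np.asarray(val, z.dtype), (logits,), bw)


@dataclass
class TFSCTrainConfig:
    epochs: int = 80
    batch_size: int = 16
    lr: float = 0.001
    seed: int = 0


def train_tfsc(samples, cfg: TFSCTrainConfig = None, val_samples=None,
               net: TFSCNet = None):
    """Train the stage classifier; deterministic under cfg.seed.

    Returns (net, history).  Zero epochs returns the freshly initialized
    (but scaler-fitted) net unchanged.  A single-class training set is
    refused.
    """
    cfg = cfg or TFSCTrainConfig()
    X = np.stack([s.features for s in samples])
    y = np.array([STAGES.index(s.label) for s in samples])
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single stage class; "
                         "need at least two")
    net = net or TFSCNet(n_features=X.shape[1], seed=cfg.seed)
    net.fit_scaler(X)
    opt = Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.logits(X[idx])
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "train_acc": correct / len(X)}
        if val_samples:
            preds = [predict_stage(net, s)[0] for s in val_samples]
            entry["val_acc"] = float(np.mean(
                [p == s.label for p, s in zip(preds, val_samples)]))
        history.append(entry)
    return net, history


def predict_stage(net: TFSCNet, sample) -> tuple:
    """(stage label, probability vector); argmax ties break to the lowest index."""
    feats = sample.features if isinstance(sample, StageSample) else \
        np.asarray(sample, np.float64)
    probs = net.predict_proba(feats)[0]
    return STAGES[int(np.argmax(probs))], probs


def evaluate_stages(predictions, labels) -> dict:
    """Accuracy, 5x5 confusion matrix and adjacent-stage error share.

    Confusion rows are the true stage, columns the predicted stage.
    ``adjacent_error_fraction`` is the share of off-diagonal mass on the
    first off-diagonals (confusions between neighboring stages).
    """
    m = np.zeros((5, 5), dtype=int)
    for p, t in zip(predictions, labels):
        m[STAGES.index(t), STAGES.index(p)] += 1
    total = m.sum()
    off = m.sum() - np.trace(m)
    adj = sum(m[i, i + 1] + m[i + 1, i] for i in range(4))
    return {
        "accuracy": float(np.trace(m) / total) if total else 0.0,
        "confusion": m,
        "adjacent_error_fraction": float(adj / off) if off else float("nan"),
    }
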