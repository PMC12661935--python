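"""End-to-end orchestration: synthesize -> train -> count -> evaluate ->
stage-classify -> flowering-dynamics report.

Each stage writes its outputs plus a ``<stage>.done`` marker containing a
hash of the stage-relevant configuration; re-running with the same config
skips completed stages and reproduces the same report.  A single global
seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
(documented, platform-stable), so stages are individually reproducible yet
statistically independent.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelConfig
from .records import frame_to_records, records_to_frame
from .synth import (SceneSpec, SeasonSpec, generate_dataset, generate_season,
                    sampling_schedule)
from .tfsc import (TFSCTrainConfig, build_stage_dataset, evaluate_stages,
                   predict_stage, train_tfsc, encode_time)
from .train import TrainConfig, evaluate_dataset, load_checkpoint, train

log = logging.getLogger(__name__)

STAGE_ORDER = ("synth", "train", "evaluate", "seasons", "tfsc", "dynamics")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "runs/run0"
    seed: int = 0
    # synthetic detection data
    n_images: int = 80
    image_size: int = 160
    n_objects_range: tuple = (4, 10)
    occlusion_rate: float = 0.0
    light_spot_rate: float = 0.0
    # detector
    width_multiple: float = 0.125
    depth_multiple: float = 0.33
    epochs: int = 30
    batch_size: int = 4
    lr: float = 0.003
    optimizer: str = "adam"
    anchor_mode: str = "kmeans"
    use_se: bool = True
    arconv_stages: tuple = ()
    use_caaft: bool = True
    conf_threshold: float = 0.25
    iou_threshold: float = 0.45
    calibrate_counts: bool = True   # fit the counting threshold on train
    # seasons / TFSC
    n_accessions: int = 12
    season_noise: float = 0.1
    tfsc_epochs: int = 80

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["n_objects_range"] = list(self.n_objects_range)
        d["arconv_stages"] = list(self.arconv_stages)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for k in ("n_objects_range", "arconv_stages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (stable across platforms)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _done_marker(out, stage):
    return Path(out) / f"{stage}.done"


def _stage_complete(out, stage, cfg_hash):
    marker = _done_marker(out, stage)
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text())["config_hash"] == cfg_hash
    except Exception:
        return False


def _mark_done(out, stage, cfg_hash):
    _done_marker(out, stage).write_text(json.dumps(
        {"config_hash": cfg_hash, "stage": stage}))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the final report dict.

    Completed stages (matching config hash) are skipped.  Any stage error
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    (out / "manifest.json").write_text(json.dumps({
        "config": cfg.to_dict(), "config_hash": cfg_hash, "seed": cfg.seed,
        "numpy": np.__version__,
    }, indent=2))
    report = {}

    data_dir = out / "data"
    ckpt = out / "detector.npz"
    seasons_csv = out / "seasons.csv"

    # ---- synth ----------------------------------------------------------
    if not _stage_complete(out, "synth", cfg_hash):
        try:
            spec = SceneSpec(image_size=cfg.image_size,
                             occlusion_rate=cfg.occlusion_rate,
                             light_spot_rate=cfg.light_spot_rate,
                             seed=stage_seed(cfg.seed, "synth"))
            generate_dataset(spec, cfg.n_images, data_dir,
                             n_objects_range=cfg.n_objects_range)
        except Exception as exc:
            raise PipelineError("synth", exc) from exc
        _mark_done(out, "synth", cfg_hash)

    # ---- train ----------------------------------------------------------
    model_cfg = ModelConfig(
        input_size=cfg.image_size, width_multiple=cfg.width_multiple,
        depth_multiple=cfg.depth_multiple, use_se=cfg.use_se,
        arconv_stages=cfg.arconv_stages, use_caaft=cfg.use_caaft,
        seed=stage_seed(cfg.seed, "train"))
    if not _stage_complete(out, "train", cfg_hash):
        try:
            tcfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               lr=cfg.lr, optimizer=cfg.optimizer,
                               anchor_mode=cfg.anchor_mode, cosine_lr=True,
                               ema_decay=0.997,
                               seed=stage_seed(cfg.seed, "train"))
            model, history = train(model_cfg, data_dir, tcfg,
                                   checkpoint_path=ckpt)
            pd.DataFrame(history).to_csv(out / "train_log.csv", index=False)
        except Exception as exc:
            raise PipelineError("train", exc) from exc
        _mark_done(out, "train", cfg_hash)
    model, _ = load_checkpoint(ckpt)

    # ---- evaluate -------------------------------------------------------
    if not _stage_complete(out, "evaluate", cfg_hash):
        try:
            if not (data_dir / "labels" / "test").is_dir():
                raise FileNotFoundError(f"missing labels dir under {data_dir}")
            count_t = cfg.conf_threshold
            if cfg.calibrate_counts:
                from .train import calibrate_count_threshold
                count_t, _ = calibrate_count_threshold(
                    model, data_dir, split="train", max_images=40)
            det_report = evaluate_dataset(model, data_dir, split="test",
                                          count_conf_threshold=count_t)
            det_report["count_threshold"] = count_t
            (out / "detection_report.json").write_text(
                json.dumps(det_report, indent=2, default=float))
        except Exception as exc:
            raise PipelineError("evaluate", exc) from exc
        _mark_done(out, "evaluate", cfg_hash)
    report["detection"] = json.loads((out / "detection_report.json").read_text())

    # ---- seasons --------------------------------------------------------
    if not _stage_complete(out, "seasons", cfg_hash):
        try:
            rng = np.random.Generator(np.random.PCG64(
                stage_seed(cfg.seed, "seasons")))
            records = []
            for year, start in ((2023, dt.date(2023, 10, 1)),
                                (2024, dt.date(2024, 10, 1))):
                for a in range(cfg.n_accessions):
                    spec = SeasonSpec(
                        accession_id=f"ACC{a:02d}", season_start=start,
                        peak_day=int(rng.integers(25, 46)),
                        peak_amplitude=float(rng.uniform(15, 60)),
                        noise_dispersion=cfg.season_noise,
                        seed=int(rng.integers(2 ** 31)))
                    records.extend(generate_season(
                        spec, sampling_schedule(spec, every=2, replicates=3)))
            records_to_frame(records).to_csv(seasons_csv, index=False)
        except Exception as exc:
            raise PipelineError("seasons", exc) from exc
        _mark_done(out, "seasons", cfg_hash)

    # ---- tfsc -----------------------------------------------------------
    if not _stage_complete(out, "tfsc", cfg_hash):
        try:
            records = frame_to_records(pd.read_csv(seasons_csv))
            ds = build_stage_dataset(records,
                                     seed=stage_seed(cfg.seed, "tfsc"))
            net, hist = train_tfsc(
                ds.train, TFSCTrainConfig(epochs=cfg.tfsc_epochs,
                                          seed=stage_seed(cfg.seed, "tfsc")),
                val_samples=ds.val)
            preds = [predict_stage(net, s)[0] for s in ds.test]
            stage_report = evaluate_stages(preds, [s.label for s in ds.test])
            stage_report["confusion"] = stage_report["confusion"].tolist()
            stage_report["val_accuracy"] = hist[-1].get("val_acc")
            (out / "stage_report.json").write_text(
                json.dumps(stage_report, indent=2, default=float))
            _save_tfsc(out / "tfsc.npz", net)
        except Exception as exc:
            raise PipelineError("tfsc", exc) from exc
        _mark_done(out, "tfsc", cfg_hash)
    report["stages"] = json.loads((out / "stage_report.json").read_text())

    # ---- dynamics -------------------------------------------------------
    if not _stage_complete(out, "dynamics", cfg_hash):
        try:
            net = _load_tfsc(out / "tfsc.npz")
            df = pd.read_csv(seasons_csv)
            rows = []
            for (acc, date), grp in df.groupby(["accession", "date"],
                                               sort=False):
                feats = np.array([grp["bud"].mean(), grp["b_flower"].mean(),
                                  grp["w_flower"].mean(), encode_time(date)])
                stage, probs = predict_stage(net, feats)
                rows.append({"accession": acc, "date": date,
                             "bud": grp["bud"].mean(),
                             "b_flower": grp["b_flower"].mean(),
                             "w_flower": grp["w_flower"].mean(),
                             "stage": stage,
                             **{f"p_{s}": p for s, p in
                                zip(("IFS", "EFS", "MFS", "LFS", "TFS"), probs)}})
            pd.DataFrame(rows).to_csv(out / "dynamics.csv", index=False)
        except Exception as exc:
            raise PipelineError("dynamics", exc) from exc
        _mark_done(out, "dynamics", cfg_hash)
    report["dynamics_csv"] = str(out / "dynamics.csv")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _save_tfsc(path, net):
    state = net.state_dict()
    np.savez_compressed(path, **state)


def _load_tfsc(path):
    from .tfsc import TFSCNet

    net = TFSCNet()
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
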