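"""Training loop with per-epoch dynamic-alpha assignment.

One master seed fans out into independent streams for weight
initialisation, data shuffling and augmentation.  The run manifest captures
the configuration snapshot, seeds and per-epoch log so a run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.autograd import Tensor
from .nn.optim import SGD, Adam
from .assign import AssignmentState, total_loss
from .config import ModelConfig
from .data_io import AnnotationRecord, AugmentConfig, augment, load_labels, read_manifest
from .evalcount import detection_metrics
from .model import PigletDetector, preprocess_image


@dataclass
class RunManifest:
    config: dict
    seed: int
    out_dir: str
    epochs: list = field(default_factory=list)  # per-epoch dicts
    best_epoch: int = -1
    best_map50: float = 0.0
    weights: str = ""

    def save(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


class ArrayDataset:
    """In-memory dataset of (image array, record) pairs."""

    def __init__(self, images, records):
        assert len(images) == len(records)
        self.images = images
        self.records = records

    def __len__(self):
        return len(self.images)

    @classmethod
    def from_manifest(cls, manifest_path):
        from PIL import Image

        paths = read_manifest(manifest_path)
        if not paths:
            raise ValueError(f"empty dataset manifest: {manifest_path}")
        images, records = [], []
        for p in paths:
            img = np.asarray(Image.open(p).convert("RGB"))
            images.append(img)
            records.append(load_labels(Path(p).with_suffix(".txt")))
        return cls(images, records)


def run_train(config: ModelConfig, dataset: ArrayDataset, out_dir,
              val_dataset: ArrayDataset | None = None,
              augment_config: AugmentConfig | None = None,
              eval_every: int = 10, model: PigletDetector | None = None,
              verbose: bool = False) -> tuple:
    """Train a detector; returns (model, manifest).

    The assignment exponent alpha follows the linear decay schedule,
    evaluated once per epoch; epoch indices run 0..max_epochs-1 during
    training so alpha approaches but never reaches zero mid-run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = PigletDetector(config)
    manifest = RunManifest(config.to_dict(), config.seed, str(out))
    params = model.parameters()
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate)
    else:
        opt = SGD(params, lr=config.learning_rate, momentum=config.momentum)
    state = AssignmentState(config.default_alpha, config.beta, config.topk,
                            0, config.max_epochs)
    rng = np.random.default_rng(config.seed + 1)
    val = val_dataset or dataset
    n = len(dataset)
    bs = min(config.batch_size, n)
    for epoch in range(config.max_epochs):
        state.current_epoch = epoch
        alpha = state.alpha
        # linear warmup on the learning rate
        if epoch < config.warmup_epochs:
            opt.lr = config.learning_rate * (epoch + 1) / config.warmup_epochs
        else:
            opt.lr = config.learning_rate
        model.train()
        order = rng.permutation(n)
        losses = []
        t0 = time.time()
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            imgs, recs = [], []
            for j in idx:
                img, rec = dataset.images[j], dataset.records[j]
                if augment_config is not None:
                    img, rec = augment(img, rec, augment_config,
                                       int(rng.integers(0, 2**31 - 1)))
                imgs.append(preprocess_image(img))
                recs.append(rec)
            batch = Tensor(np.stack(imgs))
            outputs = model(batch)
            loss = total_loss(outputs, recs, config, state)
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            losses.append(float(loss.total.data))
        entry = {"epoch": epoch, "alpha": alpha, "loss": float(np.mean(losses)),
                 "lr": opt.lr, "seconds": round(time.time() - t0, 2)}
        is_eval = (epoch + 1) % eval_every == 0 or epoch == config.max_epochs - 1
        if is_eval:
            m = evaluate(model, val)
            entry["val_map50"] = m.map50
            if m.map50 >= manifest.best_map50:
                manifest.best_map50 = m.map50
                manifest.best_epoch = epoch
                wpath = out / "best_weights.npz"
                model.save_weights(wpath)
                manifest.weights = str(wpath)
        manifest.epochs.append(entry)
        if verbose:
            print(f"epoch {epoch:3d} alpha={alpha:.3f} loss={entry['loss']:.4f}"
                  + (f" val_mAP50={entry.get('val_map50', float('nan')):.3f}" if is_eval else ""))
        manifest.save(out / "manifest.json")
    return model, manifest


def evaluate(model: PigletDetector, dataset: ArrayDataset,
             conf_threshold: float | None = None):
    """Detection metrics of a model over a dataset."""
    all_dets, all_gts = [], []
    # low decode threshold so the PR curve has full support
    for img, rec in zip(dataset.images, dataset.records):
        dets = model.detect(preprocess_image(img)[None], conf_threshold=0.05)[0]
        all_dets.append(dets)
        all_gts.append(rec.boxes)
    conf = model.config.conf_threshold if conf_threshold is None else conf_threshold
    return detection_metrics(all_dets, all_gts, conf, model.config.iou_threshold)
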