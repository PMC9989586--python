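"""Training and evaluation: SGD with momentum, stepped learning-rate
schedule, best-checkpoint selection by validation mean Dice.

The optimization protocol follows the published recipe for this
architecture: SGD with momentum 0.9 and weight decay 0.001, initial
learning rate 5e-3 decayed by a factor of 10 every 40 epochs, 300 epochs
with batch size 4 at full scale.  Weight decay applies to convolution and
linear weights only, not to normalization scales or biases.  All
randomness (initialization, shuffling) flows from the config seed, so a
run is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import SegmentationSample
from .losses import LossConfig, confusion, metrics, total_loss
from .network import EGTransUNet, ModelConfig, build_model
from .nn import SGD, Tensor


@dataclass
class TrainConfig:
    lr0: float = 5e-3
    momentum: float = 0.9
    weight_decay: float = 0.001
    epochs: int = 300
    batch_size: int = 4
    decay_every: int = 40
    decay_factor: float = 0.1
    seed: int = 0
    max_steps: Optional[int] = None  # optional cap on total SGD steps
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 1 or self.decay_every < 1:
            raise ValueError("epochs and decay_every must be >= 1")


@dataclass
class RunRecord:
    """Per-epoch history plus the best checkpoint of a training run."""

    epochs: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    best_checkpoint: Optional[str] = None
    config: Optional[dict] = None


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Stepped schedule: ``lr0 * decay_factor ** floor(epoch / decay_every)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


def _stack_batch(samples: Sequence[SegmentationSample]) -> Tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])[:, None, :, :].astype(np.float64)
    return images, masks


def save_checkpoint(model: EGTransUNet, path) -> None:
    """Persist weights + architecture config in one .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> EGTransUNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model


def _dataset_dice(model: EGTransUNet, samples, batch_size: int, threshold: float = 0.5):
    """Per-image metrics (model in eval mode); returns (records, means)."""
    was_training = model.training
    model.eval()
    rows = []
    try:
        for start in range(0, len(samples), batch_size):
            chunk = samples[start : start + batch_size]
            images, masks = _stack_batch(chunk)
            preds = model(Tensor(images)).data
            for s, pred, mask in zip(chunk, preds, masks):
                m = metrics(confusion(pred[0], mask[0], threshold=threshold))
                rows.append({"id": s.id, **m})
    finally:
        model.train(was_training)
    means = {k: float(np.mean([r[k] for r in rows])) for k in ("dice", "iou", "precision", "recall")}
    return rows, means


def train(
    cfg: TrainConfig,
    train_samples: Sequence[SegmentationSample],
    val_samples: Optional[Sequence[SegmentationSample]] = None,
    out_dir: Optional[str] = None,
    progress: bool = False,
) -> Tuple[EGTransUNet, RunRecord]:
    """Train a model; select the best checkpoint by validation mean Dice.

    Without a validation set the training set doubles as the selection
    set (useful for overfitting sanity runs).  Raises on an empty dataset
    and aborts with a diagnostic if the loss goes non-finite.
    """
    if len(train_samples) == 0:
        raise ValueError("training dataset is empty")
    selection = val_samples if val_samples else train_samples
    model = build_model(cfg.model, seed=cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    record = RunRecord(config={"train": _cfg_dict(cfg)})
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log_fh = open(out / "train_log.jsonl", "w") if out else None

    epoch_iter = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        epoch_iter = tqdm(epoch_iter, desc="epochs")

    steps_done = 0
    try:
        for epoch in epoch_iter:
            opt.lr = lr_at(epoch, cfg)
            order = shuffle_rng.permutation(len(train_samples))
            losses = []
            model.train()
            for start in range(0, len(order), cfg.batch_size):
                if cfg.max_steps is not None and steps_done >= cfg.max_steps:
                    break
                batch = [train_samples[i] for i in order[start : start + cfg.batch_size]]
                images, masks = _stack_batch(batch)
                pred = model(Tensor(images))
                loss = total_loss(masks, pred, cfg.loss)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {steps_done}: {loss.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                steps_done += 1
            _, val_means = _dataset_dice(model, selection, cfg.batch_size)
            entry = {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "val_dice": val_means["dice"],
                "val_iou": val_means["iou"],
            }
            record.epochs.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if val_means["dice"] > record.best_val_dice:
                record.best_val_dice = val_means["dice"]
                record.best_epoch = epoch
                if out:
                    record.best_checkpoint = str(out / "best.npz")
                    save_checkpoint(model, record.best_checkpoint)
            if cfg.max_steps is not None and steps_done >= cfg.max_steps:
                break
        if out:
            save_checkpoint(model, out / "last.npz")
            (out / "run_record.json").write_text(json.dumps(asdict_record(record), indent=2))
    finally:
        if log_fh:
            log_fh.close()
    return model, record


def asdict_record(record: RunRecord) -> dict:
    return {
        "epochs": record.epochs,
        "best_epoch": record.best_epoch,
        "best_val_dice": record.best_val_dice,
        "best_checkpoint": record.best_checkpoint,
        "config": record.config,
    }


def _cfg_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["model"]["input_size"] = list(d["model"]["input_size"])
    return d


def evaluate(
    model_or_checkpoint,
    samples: Sequence[SegmentationSample],
    batch_size: int = 4,
    threshold: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-image and mean Dice/IoU/precision/recall on a dataset.

    Accepts a model or a checkpoint path (any checkpoint can be evaluated
    on any dataset of matching resolution — cross-dataset evaluation).
    Means are the averages of per-image metrics.
    """
    model = (
        model_or_checkpoint
        if isinstance(model_or_checkpoint, EGTransUNet)
        else load_checkpoint(model_or_checkpoint)
    )
    h, w = model.config.input_size
    for s in samples:
        if s.mask.shape != (h, w):
            raise ValueError(
                f"sample {s.id} is {s.mask.shape}, model expects {(h, w)}; "
                "resize the dataset first"
            )
    rows, means = _dataset_dice(model, samples, batch_size, threshold=threshold)
    return pd.DataFrame(rows), {f"m_{k}": v for k, v in means.items()}
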