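"""Training harness for both networks.

Recipe defaults: Adam, initial learning rate 1e-3, decay factor 0.1 per
epoch, L2 weight decay 1e-4, 100 epochs, 80/20 patient-level
train/validation split, ED and ES samples mixed in every batch.

Two readings of "decay factor of 0.1 per epoch" exist: the literal step
schedule lr0 * 0.1**epoch extinguishes learning within a few epochs over a
100-epoch run, so the default here is time-based decay
lr(t) = lr0 / (1 + 0.1 t); the literal schedule is available via
``literal_step_decay=True``.

The loss is the sum of voxelwise cross-entropy and a soft multi-class Dice
loss over the three foreground structures — aligned with the DSC the
pipeline is evaluated on; both terms and the mix are config-exposed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import nn
from .blocks import NetworkConfig
from .io_acdc import (block_downsample_inplane, normalize_intensity,
                      stride_downsample_inplane)
from .localizer import mask_to_roi, crop_volume
from .metrics import STRUCTURES
from .nn import Adam, Module, Tensor
from .phantom import PhantomPatient


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    lr0: float = 1e-3
    decay: float = 0.1
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 4
    loss: str = "ce+dice"
    dice_weight: float = 1.0
    seed: int = 0
    val_fraction: float = 0.2
    literal_step_decay: bool = False

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("ce+dice", "ce", "dice"):
            raise ValueError(f"unsupported loss {self.loss!r}")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch index."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.literal_step_decay:
        return config.lr0 * config.decay ** epoch
    return config.lr0 / (1.0 + config.decay * epoch)


class Sample(NamedTuple):
    """One training example: channel-first input, integer target, owner."""

    x: np.ndarray          # (1, rows, cols) or (1, rows, cols, slices)
    y: np.ndarray          # matching spatial shape, integer labels
    patient_id: str


def slice_dataset(patients: Sequence[PhantomPatient],
                  slice_step: int = 1) -> list[Sample]:
    """Per-slice samples for the 2D localizer (volumes z-scored first)."""
    samples = []
    for pat in patients:
        for tag in ("ED", "ES"):
            vol, lab = pat.phase(tag)
            norm = normalize_intensity(vol).data
            for z in range(0, norm.shape[2], slice_step):
                samples.append(Sample(norm[None, :, :, z].astype(nn.DTYPE),
                                      lab.data[:, :, z].astype(np.int64),
                                      pat.patient_id))
    return samples


def crop_dataset(patients: Sequence[PhantomPatient], target: tuple[int, int],
                 margin: int = 8, downsample: int = 1) -> list[Sample]:
    """Ground-truth-guided ROI crops for the 3D segmenter (teacher forcing):
    the box comes from each phase's own label map, the crop is re-z-scored.
    ``downsample`` > 1 block-averages intensities (and subsamples labels)
    in-plane, the reduced-resolution regime of the desk-scale pipeline."""
    samples = []
    for pat in patients:
        for tag in ("ED", "ES"):
            vol, lab = pat.phase(tag)
            box = mask_to_roi(lab, margin=margin, min_size=min(target))
            crop, _ = crop_volume(normalize_intensity(vol).data, box, target)
            labels, _ = crop_volume(lab.data, box, target)
            if downsample > 1:
                crop = block_downsample_inplane(crop, downsample)
                labels = stride_downsample_inplane(labels, downsample)
            mean, sd = crop.mean(), crop.std()
            crop = (crop - mean) / (sd if sd > 1e-8 else 1.0)
            samples.append(Sample(crop[None].astype(nn.DTYPE),
                                  labels.astype(np.int64), pat.patient_id))
    return samples


def _loss(logits: Tensor, y: np.ndarray, config: TrainConfig) -> Tensor:
    n_classes = logits.shape[1]
    if config.loss == "ce":
        return nn.cross_entropy(logits, y)
    dice = nn.soft_dice_loss(logits, y, n_classes)
    if config.loss == "dice":
        return dice
    return nn.cross_entropy(logits, y) + config.dice_weight * dice


def _foreground_dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    scores = []
    for cls in STRUCTURES.values():
        p, g = pred == cls, gt == cls
        denom = p.sum() + g.sum()
        scores.append(1.0 if denom == 0 else 2.0 * np.count_nonzero(p & g) / denom)
    return float(np.mean(scores))


def split_patients(patient_ids: Sequence[str], val_fraction: float,
                   seed: int) -> tuple[list[str], list[str]]:
    """Deterministic patient-level split; returns (train_ids, val_ids)."""
    ids = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = int(round(val_fraction * len(ids)))
    val = sorted(ids[i] for i in perm[:n_val])
    train = sorted(ids[i] for i in perm[n_val:])
    return train, val


def train(network: Module, dataset: Sequence[Sample], config: TrainConfig,
          split: tuple[Sequence[str], Sequence[str]] | None = None,
          verbose: bool = False) -> tuple[dict, pd.DataFrame]:
    """Train a network; returns (best-validation weights, history).

    The split is patient-level: no patient contributes samples to both
    partitions (an explicit overlapping ``split`` is rejected naming the
    offending patient). History records per-epoch learning rate, training
    loss, validation loss and validation mean foreground DSC; the returned
    weights are from the epoch with the best validation DSC (the final
    epoch when there is no validation partition), and are also loaded back
    into the network.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    if split is None:
        train_ids, val_ids = split_patients([s.patient_id for s in dataset],
                                            config.val_fraction, config.seed)
    else:
        train_ids, val_ids = (sorted(set(split[0])), sorted(set(split[1])))
        overlap = set(train_ids) & set(val_ids)
        if overlap:
            raise ValueError(
                f"patient-level leakage across the split: {sorted(overlap)[0]!r} "
                f"appears in both partitions")
    train_set = [s for s in dataset if s.patient_id in set(train_ids)]
    val_set = [s for s in dataset if s.patient_id in set(val_ids)]
    if not train_set:
        raise ValueError("training partition is empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.lr0, weight_decay=config.weight_decay)
    history = []
    best = {"dsc": -np.inf, "state": network.state_dict(), "epoch": -1}
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(len(train_set))
        network.train(True)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            x = Tensor(np.stack([s.x for s in batch]))
            y = np.stack([s.y for s in batch])
            logits = network(x)
            loss = _loss(logits, y, config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))

        val_loss, val_dsc = np.nan, np.nan
        if val_set:
            network.eval()
            vlosses, vdscs = [], []
            for start in range(0, len(val_set), config.batch_size):
                chunk = val_set[start:start + config.batch_size]
                logits = network(Tensor(np.stack([s.x for s in chunk])))
                yv = np.stack([s.y for s in chunk])
                vlosses.extend([float(_loss(logits, yv, config).data)] * len(chunk))
                pred = logits.data.argmax(axis=1)
                vdscs.extend(_foreground_dsc(pred[i], chunk[i].y)
                             for i in range(len(chunk)))
            val_loss, val_dsc = float(np.mean(vlosses)), float(np.mean(vdscs))
            if val_dsc > best["dsc"]:
                best = {"dsc": val_dsc, "state": network.state_dict(), "epoch": epoch}
        history.append({"epoch": epoch, "lr": opt.lr, "train_loss": train_loss,
                        "val_loss": val_loss, "val_mean_dsc": val_dsc})
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  train {train_loss:.4f}  "
                  f"val {val_loss:.4f}  val DSC {val_dsc:.4f}")
    if not val_set:
        best = {"dsc": np.nan, "state": network.state_dict(), "epoch": config.epochs - 1}
    network.load_state_dict(best["state"])
    network.eval()
    return best["state"], pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict, net_config: NetworkConfig,
                    train_config: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    """Weights plus full configuration and seed, as a .npz archive."""
    meta = {"network": asdict(net_config),
            "training": asdict(train_config) if train_config else None,
            "seed": net_config.seed, **(extra or {})}
    np.savez(Path(path), __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[dict, NetworkConfig, dict]:
    """Returns (weights, network config, full metadata dict)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net_cfg = dict(meta["network"])
    net_cfg["atrous_rates"] = tuple(net_cfg["atrous_rates"])
    net_cfg["fire_specs"] = tuple(tuple(t) for t in net_cfg["fire_specs"])
    return state, NetworkConfig(**net_cfg), meta
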