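"""End-to-end phantom study orchestration.

One place ties the stages together — simulate a cohort, train the coarse
localizer and the 3D segmenter, run the cascade on held-out patients and
score it — so the command-line interface, the test suite and the
reproduction script all execute the identical study.

The ``desk_study_config`` preset is the single-CPU problem size: the full
architecture (nine fire modules, three pooling stages, atrous rates 4/8/12,
attention-gated residual UNet) at reduced channel widths, the segmenter
operating on 2x in-plane downsampled 128x128 crops, and short (~10 epoch)
training schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import NetworkConfig
from .cascade import run_cascade, segment_whole_volume

from .localizer import SqueezeDeepLab, build_localizer
from .metrics import MetricsReport, evaluate
from .phantom import PhantomPatient, generate_cohort
from .presets import desk_localizer_config, desk_segmenter_config
from .segmenter import ARU3D, build_3daru
from .trainer import TrainConfig, crop_dataset, slice_dataset, split_patients, train


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one phantom training study."""

    loc_network: NetworkConfig
    seg_network: NetworkConfig
    loc_training: TrainConfig
    seg_training: TrainConfig
    n_patients: int = 40
    margin: int = 8
    crop_target: tuple[int, int] = (128, 128)
    seg_downsample: int = 2
    slice_step: int = 2
    holdout_fraction: float = 0.2
    seed: int = 0


def desk_study_config(seed: int = 0, n_patients: int = 40,
                      loc_epochs: int = 8, seg_epochs: int = 20) -> StudyConfig:
    # 96-voxel crops bound any phantom heart with the default margin; the
    # segmenter then sees 48x48x10 inputs after the 2x in-plane reduction
    return StudyConfig(
        loc_network=desk_localizer_config(seed),
        seg_network=desk_segmenter_config(seed),
        loc_training=TrainConfig(epochs=loc_epochs, batch_size=8, seed=seed),
        seg_training=TrainConfig(epochs=seg_epochs, batch_size=4, seed=seed),
        n_patients=n_patients, crop_target=(96, 96), seed=seed)


@dataclass
class StudyResult:
    loc_net: SqueezeDeepLab
    seg_net: ARU3D
    loc_history: pd.DataFrame
    seg_history: pd.DataFrame
    train_ids: list[str]
    holdout_ids: list[str]
    patients: list[PhantomPatient] = field(repr=False)

    def holdout_patients(self) -> list[PhantomPatient]:
        ids = set(self.holdout_ids)
        return [p for p in self.patients if p.patient_id in ids]


def train_study(config: StudyConfig, patients: list[PhantomPatient] | None = None,
                verbose: bool = False) -> StudyResult:
    """Simulate (unless given) a cohort, hold out patients, train both stages.

    The holdout is a patient-level split made before any training; inside
    the training partition each network applies its own 80/20
    train/validation split for best-epoch selection.
    """
    if patients is None:
        patients = generate_cohort(config.n_patients, seed=config.seed)
    ids = [p.patient_id for p in patients]
    train_ids, holdout_ids = split_patients(ids, config.holdout_fraction,
                                            seed=config.seed + 1)
    train_patients = [p for p in patients if p.patient_id in set(train_ids)]

    loc_net = build_localizer(config.loc_network)
    loc_data = slice_dataset(train_patients, slice_step=config.slice_step)
    _, loc_hist = train(loc_net, loc_data, config.loc_training, verbose=verbose)

    seg_net = build_3daru(config.seg_network)
    seg_data = crop_dataset(train_patients, config.crop_target,
                            margin=config.margin, downsample=config.seg_downsample)
    _, seg_hist = train(seg_net, seg_data, config.seg_training, verbose=verbose)
    return StudyResult(loc_net, seg_net, loc_hist, seg_hist,
                       train_ids, holdout_ids, patients)


def evaluate_cascade(result: StudyResult, config: StudyConfig,
                     whole_volume_baseline: bool = True
                     ) -> tuple[MetricsReport, MetricsReport | None]:
    """Score the cascade on the held-out patients; optionally also the
    same segmenter applied to uncropped volumes (the single-stage baseline).
    """
    preds, gts, whole_preds = [], [], []
    for pat in result.holdout_patients():
        for tag in ("ED", "ES"):
            vol, lab = pat.phase(tag)
            seg = run_cascade(result.loc_net, result.seg_net, vol,
                              margin=config.margin, target=config.crop_target,
                              seg_downsample=config.seg_downsample)
            preds.append((pat.patient_id, tag, seg))
            gts.append((pat.patient_id, tag, lab))
            if whole_volume_baseline:
                whole = segment_whole_volume(result.seg_net, vol,
                                             seg_downsample=config.seg_downsample)
                whole_preds.append((pat.patient_id, tag, whole))
    cascade_report = evaluate(preds, gts)
    whole_report = evaluate(whole_preds, gts) if whole_volume_baseline else None
    return cascade_report, whole_report


def localizer_foreground_recall(result: StudyResult) -> float:
    """Fraction of held-out foreground voxels the coarse mask recovers
    (any structure, union over classes)."""
    from .io_acdc import normalize_intensity
    from .localizer import predict_mask

    tp = total = 0
    for pat in result.holdout_patients():
        for tag in ("ED", "ES"):
            vol, lab = pat.phase(tag)
            mask = predict_mask(result.loc_net, normalize_intensity(vol))
            fg = lab.data > 0
            tp += int(np.count_nonzero((mask.data > 0) & fg))
            total += int(np.count_nonzero(fg))
    return tp / total if total else float("nan")
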