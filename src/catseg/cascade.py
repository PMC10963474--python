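"""The full two-stage pipeline: normalize, localize, crop, segment, paste back.

Labels inside the ROI come from the 3D segmenter through the exact inverse
of the recorded crop geometry; every voxel outside the ROI is background.
ED and ES volumes are processed independently through the same weights.
"""

from __future__ import annotations

import numpy as np

from .io_acdc import (CardiacVolume, LabelMap, block_downsample_inplane,
                      normalize_intensity, repeat_upsample_inplane)
from .localizer import (CropTransform, ROIBox, SqueezeDeepLab, crop_volume,
                        mask_to_roi, predict_mask)
from .segmenter import ARU3D, segment_crop


class CascadeError(RuntimeError):
    """A stage of the cascade failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"cascade stage '{stage}' failed: {cause}")
        self.stage = stage


def paste_back(crop_labels: LabelMap | np.ndarray, transform: CropTransform) -> LabelMap:
    """Invert a crop: place crop labels at their original in-plane position,
    background (0) everywhere else; padding regions are discarded."""
    data = crop_labels.data if isinstance(crop_labels, LabelMap) else np.asarray(crop_labels)
    if data.shape != transform.crop_shape:
        raise ValueError(
            f"crop geometry mismatch: got labels of shape {data.shape}, "
            f"transform expects {transform.crop_shape} "
            f"(box {transform.box}, target {transform.target}, "
            f"full {transform.full_shape})")
    box, (pr, pc), (orr, oc) = transform.box, transform.pad_before, transform.crop_offset
    h, w = box.shape
    th, tc = transform.target
    eff_h, eff_w = min(h, th), min(w, tc)
    full = np.zeros(transform.full_shape, dtype=data.dtype)
    core = data[pr:pr + eff_h, pc:pc + eff_w]
    full[box.r0 + orr:box.r0 + orr + eff_h, box.c0 + oc:box.c0 + oc + eff_w] = core
    return LabelMap(full)


def run_cascade(loc_net: SqueezeDeepLab, seg_net: ARU3D, volume: CardiacVolume,
                margin: int = 8, target: tuple[int, int] = (128, 128),
                min_size: int | None = None, box: ROIBox | None = None,
                seg_downsample: int = 1) -> LabelMap:
    """Full-resolution segmentation of one volume.

    ``box`` overrides the localization stage (e.g. a ground-truth-derived or
    full-grid box); otherwise the coarse mask of the localizer is converted
    to an ROI. The crop is re-normalized before the 3D segmenter, matching
    how the segmenter is trained. ``seg_downsample`` > 1 runs the segmenter
    at reduced in-plane resolution (labels are restored by nearest-neighbour
    upsampling before paste-back), matching a segmenter trained with the
    same ``downsample`` factor.
    """
    min_size = min(target) if min_size is None else min_size

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise CascadeError(name, exc) from exc

    norm = stage("normalize", lambda: normalize_intensity(volume))
    if box is None:
        mask = stage("localize", lambda: predict_mask(loc_net, norm))
        box = stage("roi", lambda: mask_to_roi(mask, margin=margin, min_size=min_size))
    crop, transform = stage("crop", lambda: crop_volume(norm.data, box, target))
    if seg_downsample > 1:
        crop = stage("downsample", lambda: block_downsample_inplane(crop, seg_downsample))
    crop_vol = stage("crop-normalize", lambda: normalize_intensity(
        CardiacVolume(crop, volume.spacing, phase=volume.phase,
                      patient_id=volume.patient_id)))
    labels, _ = stage("segment", lambda: segment_crop(seg_net, crop_vol))
    crop_labels = labels.data
    if seg_downsample > 1:
        crop_labels = stage("upsample", lambda: repeat_upsample_inplane(
            labels.data, seg_downsample))
    out = stage("paste", lambda: paste_back(crop_labels, transform))
    return LabelMap(out.data, volume.spacing)


def segment_whole_volume(seg_net: ARU3D, volume: CardiacVolume,
                         seg_downsample: int = 1) -> LabelMap:
    """Apply the 3D segmenter to the uncropped volume (the single-stage
    baseline the cascade is compared against)."""
    data = normalize_intensity(volume).data
    if seg_downsample > 1:
        data = block_downsample_inplane(data, seg_downsample)
    # second z-score mirrors the cascade's crop-normalize stage exactly
    norm = normalize_intensity(CardiacVolume(data, volume.spacing))
    labels, _ = segment_crop(seg_net, norm)
    out = labels.data
    if seg_downsample > 1:
        out = repeat_upsample_inplane(out, seg_downsample)
    return LabelMap(out, volume.spacing)
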