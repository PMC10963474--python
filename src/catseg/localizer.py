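"""Coarse ROI localization: a SqueezeNet-backboned DeepLabv3+-style
slice-wise network, mask-to-box conversion, and prismatic cropping.

The localizer predicts all four classes slice by slice; the ROI is the
in-plane bounding box of the union of the three foreground structures over
all slices (one box per volume, so the 3D crop is prismatic), expanded by a
margin and grown to a minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import ASPP, FireModule, NetworkConfig
from .io_acdc import CardiacVolume, LabelMap
from .nn import Conv, Module, Tensor

#: How the nine fire modules are distributed over the three pooling stages.
FIRE_GROUPS = (2, 3, 4)


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned in-plane bounding box shared by all slices of a volume;
    0-based half-open bounds."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self):
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ValueError(f"degenerate ROI box {self}")

    def validate(self, rows: int, cols: int) -> "ROIBox":
        if self.r1 > rows or self.c1 > cols:
            raise ValueError(f"{self} exceeds grid {rows}x{cols}")
        return self

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    def to_dict(self) -> dict:
        return {"r0": self.r0, "r1": self.r1, "c0": self.c0, "c1": self.c1}


class SqueezeDeepLab(Module):
    """Slice-wise semantic segmentation network for coarse localization.

    Encoder: a convolutional stem followed by nine fire modules interspersed
    with three max-pooling stages (output stride 8). The modified ASPP
    (dilated depthwise-separable branches plus a max-pooling branch) merges
    multi-scale context; the decoder fuses one low-level encoder feature
    (taken after the first pooling stage) and upsamples back to input
    resolution, emitting a 4-class score map per slice.
    """

    def __init__(self, config: NetworkConfig):
        super().__init__()
        rng = config.rng()
        if len(config.fire_specs) != sum(FIRE_GROUPS):
            raise ValueError(
                f"expected {sum(FIRE_GROUPS)} fire specs, got {len(config.fire_specs)}")
        self.config = config
        self.stem = Conv(1, config.stem_channels, (3, 3), rng, padding=1)
        self.stem_bn = nn.BatchNorm(config.stem_channels)
        specs = list(config.fire_specs)
        groups: list[list[FireModule]] = []
        ch = config.stem_channels
        for g in FIRE_GROUPS:
            group = []
            for s, e1, e3 in specs[:g]:
                group.append(FireModule(ch, s, e1, e3, rng))
                ch = e1 + e3
            specs = specs[g:]
            groups.append(group)
        self.group1, self.group2, self.group3 = groups
        low_ch = self.group1[-1].out_channels
        self.aspp = ASPP(ch, config.aspp_out_channels, config.atrous_rates, rng)
        self.low_proj = Conv(low_ch, config.low_level_channels, (1, 1), rng)
        self.low_bn = nn.BatchNorm(config.low_level_channels)
        dec_in = config.aspp_out_channels + config.low_level_channels
        self.dec1 = Conv(dec_in, config.decoder_channels, (3, 3), rng, padding=1)
        self.dec1_bn = nn.BatchNorm(config.decoder_channels)
        self.dec2 = Conv(config.decoder_channels, config.decoder_channels, (3, 3), rng, padding=1)
        self.dec2_bn = nn.BatchNorm(config.decoder_channels)
        self.head = Conv(config.decoder_channels, config.n_classes, (1, 1), rng)

    @property
    def fire_modules(self) -> list[FireModule]:
        return list(self.group1) + list(self.group2) + list(self.group3)

    @property
    def n_pool_stages(self) -> int:
        return len(FIRE_GROUPS)

    def forward(self, x: Tensor) -> Tensor:
        rows, cols = x.shape[2], x.shape[3]
        stride = 2 ** self.n_pool_stages
        if rows % stride or cols % stride:
            raise ValueError(f"input {rows}x{cols} must be divisible by {stride}")
        h = nn.relu(self.stem_bn(self.stem(x)))
        h = nn.max_pool2d(h)
        for fire in self.group1:
            h = fire(h)
        low = h  # stride-2 low-level feature for the decoder
        h = nn.max_pool2d(h)
        for fire in self.group2:
            h = fire(h)
        h = nn.max_pool2d(h)
        for fire in self.group3:
            h = fire(h)
        h = self.aspp(h)
        h = nn.upsample_linear2x(nn.upsample_linear2x(h, (2, 3)), (2, 3))
        low = nn.relu(self.low_bn(self.low_proj(low)))
        h = nn.concat([h, low], axis=1)
        h = nn.relu(self.dec1_bn(self.dec1(h)))
        h = nn.relu(self.dec2_bn(self.dec2(h)))
        h = nn.upsample_linear2x(h, (2, 3))
        return self.head(h)


def build_localizer(config: NetworkConfig) -> SqueezeDeepLab:
    return SqueezeDeepLab(config)


def _check_normalized(data: np.ndarray) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError("input volume contains non-finite values")
    mean, sd = float(data.mean()), float(data.std())
    if abs(mean) > 0.05 or abs(sd - 1.0) > 0.05:
        raise ValueError(
            f"input volume is not z-score normalized (mean {mean:.3f}, SD {sd:.3f}); "
            f"apply io_acdc.normalize_intensity first")


def predict_mask(network: SqueezeDeepLab, volume: CardiacVolume,
                 batch_size: int = 8) -> LabelMap:
    """Slice-wise forward pass, voxelwise argmax (ties -> lowest class index)."""
    _check_normalized(volume.data)
    was_training = network.training
    network.eval()
    try:
        slices = np.moveaxis(volume.data, 2, 0)[:, None].astype(nn.DTYPE)  # (S,1,H,W)
        out = []
        for i in range(0, slices.shape[0], batch_size):
            scores = network(Tensor(slices[i:i + batch_size])).data
            out.append(scores.argmax(axis=1))
        mask = np.moveaxis(np.concatenate(out, axis=0), 0, 2)
    finally:
        network.train(was_training)
    return LabelMap(mask.astype(np.int16), volume.spacing)


def mask_to_roi(mask: LabelMap | np.ndarray, margin: int = 8,
                min_size: int = 128) -> ROIBox:
    """Tight in-plane bounds of the foreground union over all slices,
    expanded by ``margin``, clipped to the grid, then symmetrically grown to
    ``min_size`` per axis. An empty mask yields a centered ``min_size`` box.
    """
    data = mask.data if isinstance(mask, LabelMap) else np.asarray(mask)
    if margin < 0 or min_size < 0:
        raise ValueError("margin and min_size must be >= 0")
    rows, cols = data.shape[:2]
    if min_size > min(rows, cols):
        raise ValueError(f"min_size {min_size} exceeds grid {rows}x{cols}")
    fg = (data > 0).any(axis=2) if data.ndim == 3 else (data > 0)
    if not fg.any():
        if min_size == 0:
            raise ValueError("empty mask with min_size 0 gives no ROI")
        r0 = (rows - min_size) // 2
        c0 = (cols - min_size) // 2
        return ROIBox(r0, r0 + min_size, c0, c0 + min_size)
    rr = np.flatnonzero(fg.any(axis=1))
    cc = np.flatnonzero(fg.any(axis=0))
    bounds = []
    for lo, hi, n in ((rr[0], rr[-1] + 1, rows), (cc[0], cc[-1] + 1, cols)):
        lo = max(0, int(lo) - margin)
        hi = min(n, int(hi) + margin)
        grow = min_size - (hi - lo)
        if grow > 0:
            lo -= grow // 2
            hi += grow - grow // 2
            if lo < 0:
                hi -= lo
                lo = 0
            if hi > n:
                lo -= hi - n
                hi = n
        bounds.append((lo, hi))
    (r0, r1), (c0, c1) = bounds
    return ROIBox(r0, r1, c0, c1).validate(rows, cols)


@dataclass(frozen=True)
class CropTransform:
    """Geometry of a crop: enough to invert it exactly with paste_back."""

    box: ROIBox
    full_shape: tuple[int, int, int]
    target: tuple[int, int]
    pad_before: tuple[int, int]     # zero when the box is >= target per axis
    crop_offset: tuple[int, int]    # center-crop offset when box > target

    @property
    def crop_shape(self) -> tuple[int, int, int]:
        return (self.target[0], self.target[1], self.full_shape[2])


def _center_fit(length: int, target: int) -> tuple[int, int]:
    """(pad_before, crop_offset) to center-fit ``length`` into ``target``;
    when padding, the smaller pad goes first."""
    if length < target:
        return ((target - length) // 2, 0)
    return (0, (length - target) // 2)


def crop_volume(data, box: ROIBox, target: tuple[int, int],
                fill: str = "auto") -> tuple[np.ndarray, CropTransform]:
    """Extract ``box`` on every slice, then center-pad or center-crop to
    ``target`` in-plane. Volumes are padded with their minimum intensity,
    label maps with background (``fill='auto'`` picks by dtype). Returns the
    result and the transform needed to paste it back.
    """
    if isinstance(data, CardiacVolume):
        arr = data.data
    elif isinstance(data, LabelMap):
        arr = data.data
    else:
        arr = np.asarray(data)
    rows, cols, slices = arr.shape
    box.validate(rows, cols)
    tr, tc = int(target[0]), int(target[1])
    if tr < 1 or tc < 1:
        raise ValueError(f"degenerate crop target {target}")
    sub = arr[box.r0:box.r1, box.c0:box.c1]
    h, w = sub.shape[:2]
    pr, orr = _center_fit(h, tr)
    pc, oc = _center_fit(w, tc)
    if fill == "auto":
        is_labels = np.issubdtype(arr.dtype, np.integer)
        fill_value = 0 if is_labels else float(arr.min())
    else:
        fill_value = fill
    out = np.full((tr, tc, slices), fill_value, dtype=arr.dtype)
    src = sub[orr:orr + min(h, tr), oc:oc + min(w, tc)]
    out[pr:pr + src.shape[0], pc:pc + src.shape[1]] = src
    t = CropTransform(box, (rows, cols, slices), (tr, tc), (pr, pc), (orr, oc))
    return out, t
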