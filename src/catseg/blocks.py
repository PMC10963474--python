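"""Network building blocks: fire module, modified ASPP, full pre-activation
3D residual block, and the spatial attention gate.

All blocks are pure in-memory components over the autodiff engine in
:mod:`catseg.nn`; :func:`catseg.nn.count_parameters` gives exact trainable
scalar counts for any of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Conv, Module, Tensor

#: SqueezeNet-v1.1-style ladder of (squeeze, expand1x1, expand3x3) channel
#: triples; nine modules interspersed with three max-pooling stages.
DEFAULT_FIRE_SPECS = (
    (16, 64, 64), (16, 64, 64),
    (32, 128, 128), (32, 128, 128), (48, 192, 192),
    (48, 192, 192), (64, 256, 256), (64, 256, 256), (64, 256, 256),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Shared hyperparameters for the localizer and the 3D segmenter.

    ``atrous_rates`` are the ASPP dilation rates (default 4, 8, 12, found
    suitable for small structures such as the systolic RV). ``depth`` and
    ``base_channels`` size the 3D residual UNet (channels double per level);
    ``attention_inter_channels`` is the intermediate width of the attention
    gates (``None`` = half the skip channels). ``fire_specs`` is the ladder
    of nine (squeeze, expand1x1, expand3x3) triples of the localizer encoder.
    """

    atrous_rates: tuple[int, ...] = (4, 8, 12)
    fire_specs: tuple[tuple[int, int, int], ...] = DEFAULT_FIRE_SPECS
    aspp_out_channels: int = 256
    depth: int = 4
    base_channels: int = 32
    attention_inter_channels: int | None = None
    stem_channels: int = 64
    decoder_channels: int = 64
    low_level_channels: int = 32
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self):
        rates = tuple(int(r) for r in self.atrous_rates)
        if not rates or rates[0] <= 0 or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError(f"atrous_rates must be strictly increasing positive integers, got {rates}")
        object.__setattr__(self, "atrous_rates", rates)
        object.__setattr__(self, "fire_specs", tuple(tuple(int(c) for c in t) for t in self.fire_specs))
        for t in self.fire_specs:
            if len(t) != 3 or any(c < 1 for c in t):
                raise ValueError(f"fire spec must be three channel counts >= 1, got {t}")
        for name in ("aspp_out_channels", "base_channels", "stem_channels",
                     "decoder_channels", "low_level_channels", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.attention_inter_channels is not None and self.attention_inter_channels < 1:
            raise ValueError("attention_inter_channels must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class FireModule(Module):
    """Squeeze (1x1) convolution feeding parallel 1x1 and 3x3 expand
    convolutions whose rectified outputs are concatenated; spatial size is
    preserved (3x3 padding 1). Output channels = e1 + e3."""

    def __init__(self, in_channels: int, squeeze: int, expand1: int, expand3: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = expand1 + expand3
        self.squeeze = Conv(in_channels, squeeze, (1, 1), rng, bias=bias)
        self.expand1 = Conv(squeeze, expand1, (1, 1), rng, bias=bias)
        self.expand3 = Conv(squeeze, expand3, (3, 3), rng, padding=1, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        s = nn.relu(self.squeeze(x))
        return nn.concat([nn.relu(self.expand1(s)), nn.relu(self.expand3(s))], axis=1)


def fire_forward(x: Tensor, module: FireModule) -> Tensor:
    """Functional alias for :class:`FireModule`'s forward pass."""
    return module(x)


def _pad_to(x: Tensor, rows: int, cols: int) -> Tensor:
    """Edge-pad a (N, C, H, W) tensor up to (rows, cols) (at most +1 each)."""
    if x.shape[2] < rows:
        x = nn.concat([x, x[:, :, -1:, :]], axis=2)
    if x.shape[3] < cols:
        x = nn.concat([x, x[:, :, :, -1:]], axis=3)
    return x


class ASPP(Module):
    """Modified atrous spatial pyramid pooling.

    Parallel branches over the encoder feature map: one 1x1 convolution,
    one depthwise-separable 3x3 convolution per dilation rate (padding =
    rate, so spatial size is preserved), and a max-pooling branch restored
    to the input size by nearest-neighbour upsampling. Branch outputs are
    concatenated and projected to ``out_channels`` by a 1x1 convolution.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.rates = tuple(rates)
        self.conv1 = Conv(in_channels, out_channels, (1, 1), rng)
        self.bn1 = nn.BatchNorm(out_channels)
        self.depthwise = [Conv(in_channels, in_channels, (3, 3), rng, padding=r,
                               dilation=r, groups=in_channels, bias=False)
                          for r in self.rates]
        self.pointwise = [Conv(in_channels, out_channels, (1, 1), rng) for _ in self.rates]
        self.bn_rates = [nn.BatchNorm(out_channels) for _ in self.rates]
        self.pool_conv = Conv(in_channels, out_channels, (1, 1), rng)
        self.bn_pool = nn.BatchNorm(out_channels)
        self.project = Conv(out_channels * self.n_branches, out_channels, (1, 1), rng)
        self.bn_project = nn.BatchNorm(out_channels)

    @property
    def n_branches(self) -> int:
        """Parallel branches before concatenation: 1x1 + one per rate + pooling."""
        return 2 + len(self.rates)

    def forward(self, x: Tensor) -> Tensor:
        rows, cols = x.shape[2], x.shape[3]
        need = max(self.rates) + 1
        if min(rows, cols) < need:
            raise ValueError(
                f"ASPP input {rows}x{cols} smaller than largest dilation rate "
                f"requires (>= {need} per axis)")
        branches = [nn.relu(self.bn1(self.conv1(x)))]
        for dw, pw, bn in zip(self.depthwise, self.pointwise, self.bn_rates):
            branches.append(nn.relu(bn(pw(dw(x)))))
        pooled = nn.upsample_nearest2x(nn.max_pool2d(x), (2, 3))
        pooled = _pad_to(pooled, rows, cols)
        branches.append(nn.relu(self.bn_pool(self.pool_conv(pooled))))
        return nn.relu(self.bn_project(self.project(nn.concat(branches, axis=1))))


class ResidualBlock3D(Module):
    """Full pre-activation residual block: shortcut(x) + conv(relu(norm(
    conv(relu(norm(x)))))) with 3x3x3 kernels. The shortcut is the identity
    when channel counts match and no stride is applied, else a strided
    1x1x1 projection. Striding (in-plane) happens in the first convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 stride: tuple[int, int, int] = (1, 1, 1)):
        super().__init__()
        self.bn1 = nn.BatchNorm(in_channels)
        self.conv1 = Conv(in_channels, out_channels, (3, 3, 3), rng,
                          stride=stride, padding=1)
        self.bn2 = nn.BatchNorm(out_channels)
        self.conv2 = Conv(out_channels, out_channels, (3, 3, 3), rng, padding=1)
        if in_channels == out_channels and tuple(stride) == (1, 1, 1):
            self.shortcut = None
        else:
            self.shortcut = Conv(in_channels, out_channels, (1, 1, 1), rng,
                                 stride=stride, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(nn.relu(self.bn1(x)))
        h = self.conv2(nn.relu(self.bn2(h)))
        s = x if self.shortcut is None else self.shortcut(x)
        if s.shape != h.shape:
            raise ValueError(f"residual sum shape mismatch: shortcut {s.shape} vs branch {h.shape}")
        return s + h


class AttentionGate3D(Module):
    """Spatial attention gate on a skip connection.

    The skip feature is compressed by a strided 1x1x1 convolution to the
    gate's (half in-plane) grid, summed with the projected gating signal
    from the decoder level underneath, rectified, reduced to one channel,
    linearly resampled back to the skip grid and squashed by a sigmoid.
    The attention map alpha lies strictly in (0, 1) and multiplies the skip
    feature voxel by voxel (broadcast over channels).
    """

    def __init__(self, skip_channels: int, gate_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(1, skip_channels // 2)
        self.theta = Conv(skip_channels, inter, (1, 1, 1), rng, stride=(2, 2, 1))
        self.phi = Conv(gate_channels, inter, (1, 1, 1), rng)
        self.psi = Conv(inter, 1, (1, 1, 1), rng)

    def forward(self, skip: Tensor, gate: Tensor) -> tuple[Tensor, Tensor]:
        sr, sc, ss = skip.shape[2:]
        gr, gc, gs = gate.shape[2:]
        if (gr * 2, gc * 2, gs) != (sr, sc, ss):
            raise ValueError(
                f"gate grid {gate.shape[2:]} is not the skip grid {skip.shape[2:]} "
                f"reduced by an integer in-plane factor of 2")
        q = nn.relu(self.theta(skip) + self.phi(gate))
        logit = nn.upsample_linear2x(self.psi(q), axes=(2, 3))
        alpha = nn.sigmoid(logit)
        return nn.mul(skip, alpha), alpha


count_parameters = nn.count_parameters
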