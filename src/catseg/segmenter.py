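"""The 3D attention residual UNet that segments cropped volumes.

An encoder-decoder of full pre-activation residual blocks; every decoder
level receives its encoder skip through a spatial attention gate whose
gating signal is the decoder feature one level below. Downsampling is by
in-plane strided convolution inside the first residual block of each level,
upsampling by transposed convolution; the slice axis is never pooled (slice
counts of short-axis studies are small), so only the in-plane dimensions
must be divisible by ``2**(depth - 1)``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import AttentionGate3D, NetworkConfig, ResidualBlock3D
from .io_acdc import CardiacVolume, LabelMap
from .localizer import _check_normalized
from .nn import Conv, Module, Tensor


class ARU3D(Module):
    """3D attention residual UNet with 4-class output.

    Setting ``attention_enabled = False`` replaces every gate by a
    pass-through (alpha = 1), reducing the network to a plain residual UNet
    — the ablation hook. Attention maps of the last forward pass are kept in
    ``last_alphas`` (shallowest level first).
    """

    def __init__(self, config: NetworkConfig):
        super().__init__()
        rng = config.rng()
        d, c = config.depth, config.base_channels
        self.config = config
        self.attention_enabled = True
        self.last_alphas: list[np.ndarray] = []
        chans = [c * 2 ** i for i in range(d)]
        self.channels = chans
        self.enc = [ResidualBlock3D(1, chans[0], rng)]
        for i in range(1, d):
            self.enc.append(ResidualBlock3D(chans[i - 1], chans[i], rng, stride=(2, 2, 1)))
        self.ups = [nn.ConvTranspose(chans[i + 1], chans[i], (2, 2, 1), rng)
                    for i in range(d - 1)]
        self.gates = [AttentionGate3D(chans[i], chans[i + 1], rng,
                                      config.attention_inter_channels)
                      for i in range(d - 1)]
        # 1x1x1 fusion after the skip concat keeps the decoder residual
        # blocks at the level's native width
        self.fuse = [Conv(chans[i] * 2, chans[i], (1, 1, 1), rng)
                     for i in range(d - 1)]
        self.dec = [ResidualBlock3D(chans[i], chans[i], rng) for i in range(d - 1)]
        self.head = Conv(chans[0], config.n_classes, (1, 1, 1), rng)

    @property
    def n_attention_gates(self) -> int:
        return len(self.gates)

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        rows, cols = x.shape[2], x.shape[3]
        div = 2 ** (d - 1)
        if rows % div or cols % div:
            raise ValueError(
                f"in-plane crop {rows}x{cols} must be divisible by {div} "
                f"for depth {d}")
        skips = []
        h = x
        for block in self.enc:
            h = block(h)
            skips.append(h)
        self.last_alphas = []
        alphas = []
        for i in range(d - 2, -1, -1):
            gate = h  # decoder feature one level below the skip
            if self.attention_enabled:
                attended, alpha = self.gates[i](skips[i], gate)
                alphas.append(alpha.data)
            else:
                attended = skips[i]
            up = self.ups[i](h)
            h = self.dec[i](self.fuse[i](nn.concat([up, attended], axis=1)))
        self.last_alphas = alphas[::-1]
        return self.head(h)


def build_3daru(config: NetworkConfig) -> ARU3D:
    return ARU3D(config)


def segment_crop(network: ARU3D, crop: CardiacVolume | np.ndarray
                 ) -> tuple[LabelMap, np.ndarray]:
    """Segment one normalized crop; returns (labels, 4-class score volume).

    Voxelwise class is the highest score, ties resolved to the lowest class
    index (argmax-first semantics), matching the localizer's rule.
    """
    if isinstance(crop, CardiacVolume):
        data, spacing = crop.data, crop.spacing
    else:
        data, spacing = np.asarray(crop), (1.0, 1.0, 1.0)
    _check_normalized(data)
    was_training = network.training
    network.eval()
    try:
        x = Tensor(data[None, None].astype(nn.DTYPE))  # (1,1,R,C,S)
        scores = network(x).data[0]                    # (4,R,C,S)
    finally:
        network.train(was_training)
    labels = scores.argmax(axis=0).astype(np.int16)
    return LabelMap(labels, spacing), scores
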