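"""Named network/training presets.

``default_*`` follow the published architecture scale (SqueezeNet v1.1
fire ladder; depth-4, base-32 UNet). ``desk_*`` are width-reduced variants
of the identical architecture (same module counts, pooling stages and
atrous rates) sized so the full pipeline trains on phantom cohorts on a
single CPU in minutes; they are the presets the worked example, the test
suite and the reproduction script use.
"""

from __future__ import annotations

from .blocks import NetworkConfig
from .trainer import TrainConfig

#: Width-reduced nine-module fire ladder (squeeze, expand1x1, expand3x3).
DESK_FIRE_SPECS = (
    (4, 8, 8), (4, 8, 8),
    (6, 12, 12), (6, 12, 12), (6, 12, 12),
    (8, 16, 16), (8, 16, 16), (8, 16, 16), (8, 16, 16),
)

def default_localizer_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(seed=seed)


def default_segmenter_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(depth=4, base_channels=32, seed=seed)


def desk_localizer_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(
        fire_specs=DESK_FIRE_SPECS, aspp_out_channels=24, stem_channels=8,
        decoder_channels=16, low_level_channels=8, seed=seed)


def desk_segmenter_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(depth=3, base_channels=8, seed=seed)


def desk_train_config(seed: int = 0, epochs: int = 12, **overrides) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=4, seed=seed, **overrides)
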