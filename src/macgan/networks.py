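"""The U-shaped generator with MA-gated skips and the conditional discriminator.

Generator: a 3-D encoder/decoder with four max-pool downsamplings and a
channel schedule 16→32→64→128→256 (so a C×D×256×256 input is compressed to a
256 × D/16 × 16 × 16 bottleneck), 3×3×3 convolutions with batch norm and
ReLU throughout, linear-interpolation upsampling, and a 1×1×1 sigmoid head
producing a per-voxel foreground probability.  When ``use_ma`` is set, each
encoder feature map passes through a multi-axis attention block before being
concatenated into the decoder; with it off the model reduces to a plain
U-shaped baseline.

Discriminator: the CT condition concatenated with a (real or generated)
label map, three stride-2 convolutions each followed by dropout 0.5, global
average pooling, and a fully connected sigmoid head giving the probability
that the label is real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import MultiAxisAttention
from .nn.tensor import concatenate, relu, reshape, sigmoid, upsample_linear3d

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "Generator",
           "Discriminator", "count_parameters"]


@dataclass
class GeneratorConfig:
    in_channels: int = 1          # the windowed CT; 2 duplicates it (Fig-style)
    out_channels: int = 1
    base_channels: int = 16
    levels: int = 4
    use_ma: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.levels != 4:
            raise ValueError("the generator contract fixes 4 downsamplings")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.levels


@dataclass
class DiscriminatorConfig:
    condition_channels: int = 1
    label_channels: int = 1
    layer_channels: tuple = (32, 64, 128)
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_channels) != 3:
            raise ValueError("the discriminator has exactly 3 downsampling layers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class _ConvBlock(nn.Module):
    """3×3×3 conv + BN + ReLU."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv = nn.Conv3d(in_ch, out_ch, kernel=3, padding=1, rng=rng)
        self.bn = nn.BatchNorm3d(out_ch)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class _DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.b1 = _ConvBlock(in_ch, out_ch, rng)
        self.b2 = _ConvBlock(out_ch, out_ch, rng)

    def forward(self, x):
        return self.b2(self.b1(x))


class Generator(nn.Module):
    """Segmentation generator; input [N, C, D, H, W] with D, H, W % 16 == 0."""

    def __init__(self, config: GeneratorConfig = GeneratorConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        bc = config.base_channels
        chans = [bc * 2 ** i for i in range(config.levels + 1)]  # 16..256

        self.enc0 = _DoubleConv(config.in_channels, chans[0], rng)
        self.enc1 = _DoubleConv(chans[0], chans[1], rng)
        self.enc2 = _DoubleConv(chans[1], chans[2], rng)
        self.enc3 = _DoubleConv(chans[2], chans[3], rng)
        self.bottleneck = _DoubleConv(chans[3], chans[4], rng)

        if config.use_ma:
            self.ma0 = MultiAxisAttention(chans[0], rng=rng)
            self.ma1 = MultiAxisAttention(chans[1], rng=rng)
            self.ma2 = MultiAxisAttention(chans[2], rng=rng)
            self.ma3 = MultiAxisAttention(chans[3], rng=rng)

        self.dec3 = _DoubleConv(chans[4] + chans[3], chans[3], rng)
        self.dec2 = _DoubleConv(chans[3] + chans[2], chans[2], rng)
        self.dec1 = _DoubleConv(chans[2] + chans[1], chans[1], rng)
        self.dec0 = _DoubleConv(chans[1] + chans[0], chans[0], rng)
        self.head = nn.Conv3d(chans[0], config.out_channels, kernel=1,
                              padding=0, rng=rng)

    def _check(self, x):
        if x.ndim != 5:
            raise ValueError(f"expected [N,C,D,H,W], got rank {x.ndim}")
        d, h, w = x.shape[2:]
        if d % 16 or h % 16 or w % 16:
            raise ValueError(f"spatial dims must be divisible by 16, got "
                             f"{(d, h, w)}; pad the depth first")

    def forward(self, x, return_bottleneck=False):
        self._check(x)
        ma = self.config.use_ma
        e0 = self.enc0(x)
        e1 = self.enc1(nn.maxpool3d(e0))
        e2 = self.enc2(nn.maxpool3d(e1))
        e3 = self.enc3(nn.maxpool3d(e2))
        b = self.bottleneck(nn.maxpool3d(e3))

        s3 = self.ma3(e3) if ma else e3
        s2 = self.ma2(e2) if ma else e2
        s1 = self.ma1(e1) if ma else e1
        s0 = self.ma0(e0) if ma else e0

        d3 = self.dec3(concatenate([upsample_linear3d(b), s3], axis=1))
        d2 = self.dec2(concatenate([upsample_linear3d(d3), s2], axis=1))
        d1 = self.dec1(concatenate([upsample_linear3d(d2), s1], axis=1))
        d0 = self.dec0(concatenate([upsample_linear3d(d1), s0], axis=1))
        out = sigmoid(self.head(d0))
        return (out, b) if return_bottleneck else out


class Discriminator(nn.Module):
    """Conditional critic: P(label is real | CT condition)."""

    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        in_ch = config.condition_channels + config.label_channels
        c1, c2, c3 = config.layer_channels
        self.conv1 = nn.Conv3d(in_ch, c1, kernel=3, stride=2, padding=1, rng=rng)
        self.conv2 = nn.Conv3d(c1, c2, kernel=3, stride=2, padding=1, rng=rng)
        self.conv3 = nn.Conv3d(c2, c3, kernel=3, stride=2, padding=1, rng=rng)
        self.drop1 = nn.Dropout(config.dropout_rate, rng=rng)
        self.drop2 = nn.Dropout(config.dropout_rate, rng=rng)
        self.drop3 = nn.Dropout(config.dropout_rate, rng=rng)
        self.fc = nn.Linear(c3, 1, rng=rng)

    def forward(self, condition, label):
        if condition.shape[2:] != label.shape[2:]:
            raise ValueError(f"condition/label shapes misaligned: "
                             f"{condition.shape} vs {label.shape}")
        x = concatenate([condition, label], axis=1)
        x = self.drop1(relu(self.conv1(x)))
        x = self.drop2(relu(self.conv2(x)))
        x = self.drop3(relu(self.conv3(x)))
        pooled = nn.tmean(x, axis=(2, 3, 4))        # global average pool
        return sigmoid(reshape(self.fc(pooled), (x.shape[0],)))


def count_parameters(net: nn.Module) -> int:
    """Total trainable scalars (frozen parameters excluded)."""
    return int(sum(p.data.size for p in net.parameters() if p.requires_grad))
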