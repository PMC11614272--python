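"""Slice feature projection (FP) and multi-axis attention (MA).

FP pools a 3-D feature map along one anatomical axis (axial / sagittal /
coronal), processes the 2-D projection with convolutions against the pooled
key/query, mixes the resulting attention map back with the features, and
reduces to a per-channel gate of shape [C, 1, 1, 1].  MA runs three FP
branches (one per plane) and fuses their gates multiplicatively with the
input under learnable simplex weights β (softmax of three logits, so
Σβ = 1 holds exactly after every optimizer update):

    y = Σ_α β_α · FP_α(x) ⊙ x,    Σ_α β_α = 1.

Projecting a volume onto a plane raises the fraction of the map occupied by
a small target from O(1/n³) to O(1/n²), which is the motivation for gating
skip connections with these projections.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.tensor import (Tensor, as_tensor, concatenate, reshape, softmax,
                        tmax, tmean, tsum)

__all__ = ["PROJECTION_AXES", "project_kq", "FPBlock", "FusionWeights",
           "normalize_fusion_weights", "MultiAxisAttention"]

# axis reduced by each projection, for batched [N, C, D, H, W] maps
PROJECTION_AXES = {"axial": 2, "sagittal": 4, "coronal": 3}


def _batched(x):
    """Promote [C,D,H,W] to [1,C,D,H,W]; remember whether we did."""
    x = as_tensor(x)
    if x.ndim == 4:
        return reshape(x, (1,) + x.shape), True
    if x.ndim == 5:
        return x, False
    raise ValueError(f"expected rank-4 or rank-5 features, got rank {x.ndim}")


def project_kq(x, axis: str):
    """K = Q = Max(x) + Mean(x), pooled along the projection axis.

    Output shape per axis (batch dim preserved): axial → [C,H,W],
    sagittal → [C,D,H], coronal → [C,D,W].
    """
    if axis not in PROJECTION_AXES:
        raise ValueError(f"unknown projection axis {axis!r}")
    xb, squeezed = _batched(x)
    ax = PROJECTION_AXES[axis]
    out = tmax(xb, axis=ax) + tmean(xb, axis=ax)
    if squeezed:
        out = reshape(out, out.shape[1:])
    return out


class FPBlock(nn.Module):
    """One slice-feature-projection branch for a fixed axis.

    Parameters: a 1×1×1 value convolution on the 3-D features, two 3×3
    convolutions on the projected key (ReLU between them), and two 1×1
    fusion convolutions mapping the concat(K′, Q) channels 2C → C → C.
    """

    def __init__(self, channels: int, axis: str, rng=None):
        super().__init__()
        if axis not in PROJECTION_AXES:
            raise ValueError(f"unknown projection axis {axis!r}")
        self.axis = axis
        self.channels = channels
        rng = rng or np.random.default_rng()
        self.value = nn.Conv3d(channels, channels, kernel=1, padding=0, rng=rng)
        self.k1 = nn.Conv2d(channels, channels, kernel=3, padding=1, rng=rng)
        self.k2 = nn.Conv2d(channels, channels, kernel=3, padding=1, rng=rng)
        self.fuse1 = nn.Conv2d(2 * channels, channels, kernel=1, padding=0, rng=rng)
        self.fuse2 = nn.Conv2d(channels, channels, kernel=1, padding=0, rng=rng)

    def forward(self, x):
        """Return the per-channel gate [N, C, 1, 1, 1] (or [C,1,1,1])."""
        xb, squeezed = _batched(x)
        if xb.shape[1] != self.channels:
            raise ValueError(f"FPBlock built for {self.channels} channels, "
                             f"got {xb.shape[1]}")
        ax = PROJECTION_AXES[self.axis]
        kq = project_kq(xb, self.axis)              # [N, C, a, b]
        kp = self.k2(nn.relu(self.k1(kq)))          # K′: two 3×3 convs
        att2d = self.fuse2(nn.relu(self.fuse1(concatenate([kp, kq], axis=1))))
        # replicate along this axis's reduced dimension → R [N,C,D,H,W]
        sh = list(att2d.shape)
        sh.insert(ax, 1)
        r = reshape(att2d, tuple(sh))
        v = self.value(xb)                          # [N, C, D, H, W]
        # mixed matrix H stacks (R⊙V, x) along a pair axis; summing that
        # pair is R⊙V + x, done directly to avoid materializing the stack
        mixed = r * v + xb
        gate = tmean(mixed, axis=(2, 3, 4), keepdims=True)  # [N, C, 1, 1, 1]
        if squeezed:
            gate = reshape(gate, gate.shape[1:])
        return gate


class FusionWeights:
    """Three learnable logits whose softmax gives the simplex weights β."""

    def __init__(self, logits=(0.0, 0.0, 0.0)):
        arr = np.asarray(logits, dtype=np.float32)
        if arr.shape != (3,) or not np.all(np.isfinite(arr)):
            raise ValueError("need 3 finite logits")
        self.logits = Tensor(arr, requires_grad=True)

    @property
    def weights(self) -> Tensor:
        return softmax(self.logits)

    @property
    def beta(self) -> np.ndarray:
        return self.weights.data.copy()


def normalize_fusion_weights(logits) -> FusionWeights:
    """Wrap raw logits; β = softmax(logits) is on the simplex by construction."""
    return FusionWeights(logits)


class MultiAxisAttention(nn.Module):
    """Fuse the three FP gates with the input: y = Σ_α β_α · gate_α ⊙ x."""

    AXES = ("axial", "sagittal", "coronal")

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.fp_axial = FPBlock(channels, "axial", rng=rng)
        self.fp_sagittal = FPBlock(channels, "sagittal", rng=rng)
        self.fp_coronal = FPBlock(channels, "coronal", rng=rng)
        self.register_parameter("logits", np.zeros(3, dtype=np.float32))

    @property
    def beta(self) -> np.ndarray:
        return softmax(self.logits).data.copy()

    def forward(self, x, gates=None):
        """``gates`` overrides the FP branches (testing hook)."""
        xb, squeezed = _batched(x)
        if gates is None:
            gates = [self.fp_axial(xb), self.fp_sagittal(xb), self.fp_coronal(xb)]
        w = softmax(self.logits)
        onehots = np.eye(3, dtype=np.float32)
        y = None
        for i, gate in enumerate(gates):
            beta_i = tsum(w * Tensor(onehots[i]))   # scalar, keeps grad to logits
            term = beta_i * (as_tensor(gate) * xb)
            y = term if y is None else y + term
        if squeezed:
            y = reshape(y, y.shape[1:])
        return y
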