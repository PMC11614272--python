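"""CT preprocessing: labeled-slice cropping, HU windowing, scaling, resizing.

The preprocessing chain applied before training/inference is

    crop_to_labeled_range → apply_window → normalize01 → resize_inplane

plus a reflect depth-pad to the next multiple of 16 at network entry (the
encoder halves the spatial dimensions four times).  The window defaults to
the [−30, 170] HU display range used for liver CT (window level 70 / width
200 in level/width terms); everything below shows as black, above as white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume import Volume

__all__ = ["WindowSpec", "crop_to_labeled_range", "apply_window",
           "normalize01", "resize_inplane", "pad_depth_to_multiple",
           "unpad_depth", "preprocess_case"]


@dataclass
class WindowSpec:
    """Clipping range in Hounsfield units."""

    lower: float = -30.0
    upper: float = 170.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"window lower must be < upper, got {self}")

    @property
    def level(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def crop_to_labeled_range(vol: Volume, labels: Volume):
    """Drop depth slices outside the first..last slice containing any label.

    Keeps every nonzero label voxel; the output depth equals
    ``last_nonzero − first_nonzero + 1``.
    """
    if vol.shape != labels.shape:
        raise ValueError(f"shape mismatch {vol.shape} vs {labels.shape}")
    nz = np.flatnonzero(np.any(labels.data != 0, axis=(1, 2)))
    if nz.size == 0:
        raise ValueError("label map contains no nonzero voxel")
    lo, hi = int(nz[0]), int(nz[-1]) + 1
    return vol.with_data(vol.data[lo:hi]), labels.with_data(labels.data[lo:hi])


def apply_window(vol: Volume, window: WindowSpec = WindowSpec()) -> Volume:
    """Clip intensities to the window range; interior values unchanged."""
    return vol.with_data(np.clip(vol.data, window.lower, window.upper))


def normalize01(vol: Volume, window: WindowSpec = WindowSpec()) -> Volume:
    """Map the fixed window range linearly onto [0, 1].

    The scale is the window, not the per-volume min/max, so intensities are
    comparable across cases.
    """
    data = (vol.data.astype(np.float32) - window.lower) / window.width
    return vol.with_data(data)


def resize_inplane(vol: Volume, target: int, is_label: bool = False) -> Volume:
    """Resize each axial slice to ``target×target``.

    Images use linear interpolation; label maps use nearest-neighbor so the
    value set is preserved.  In-plane spacing is rescaled accordingly.
    """
    if target < 16:
        raise ValueError(f"target must be >= 16, got {target}")
    d, h, w = vol.shape
    if (h, w) == (target, target):
        return vol.with_data(vol.data.copy())
    order = 0 if is_label else 1
    out = _sk_resize(vol.data.astype(np.float32), (d, target, target),
                     order=order, preserve_range=True, anti_aliasing=False)
    if is_label:
        out = np.rint(out).astype(vol.data.dtype)
    else:
        out = out.astype(np.float32)
    sp = (vol.spacing[0], vol.spacing[1] * h / target, vol.spacing[2] * w / target)
    return Volume(out, sp, vol.affine.copy())


def pad_depth_to_multiple(vol: Volume, multiple: int = 16):
    """Reflect-pad the depth axis up to the next multiple of ``multiple``.

    Returns ``(padded_volume, pad_amount)``; ``pad_amount`` lets predictions
    be un-padded back to the native depth.
    """
    d = vol.shape[0]
    pad = (-d) % multiple
    if pad == 0:
        return vol.with_data(vol.data.copy()), 0
    data = np.pad(vol.data, ((0, pad), (0, 0), (0, 0)), mode="reflect")
    return vol.with_data(data), pad


def unpad_depth(data: np.ndarray, pad: int) -> np.ndarray:
    return data if pad == 0 else data[: data.shape[0] - pad]


def preprocess_case(img: Volume, labels: Volume, window: WindowSpec = WindowSpec(),
                    target: int | None = None):
    """Full chain: crop → window → normalize → optional in-plane resize."""
    img, labels = crop_to_labeled_range(img, labels)
    img = normalize01(apply_window(img, window), window)
    if target is not None:
        img = resize_inplane(img, target, is_label=False)
        labels = resize_inplane(labels, target, is_label=True)
    return img, labels
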