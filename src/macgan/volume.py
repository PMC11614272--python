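"""Volumes: rank-3 voxel arrays with spacing/affine metadata, NIfTI I/O.

Arrays are indexed ``[depth, height, width]``, 0-based; an "axial plane" is a
fixed-depth slice.  Intensities are Hounsfield units until windowed and
normalized.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D scalar field plus geometry.

    Attributes
    ----------
    data : ndarray [D, H, W]
        Voxel values (HU for raw CT, [0, 1] after normalization, small
        integers for label maps).
    spacing : tuple of float
        Voxel edge lengths in mm along (D, H, W); all positive.
    affine : ndarray [4, 4]
        Voxel-to-world orientation matrix.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be rank 3, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data) -> "Volume":
        return Volume(data, self.spacing, self.affine.copy())


def read_volume(path) -> Volume:
    """Load a NIfTI file as a :class:`Volume`.

    The array is used in the file's stored [D, H, W] order; spacing comes
    from the header zooms.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as e:  # malformed file
        raise ValueError(f"cannot read NIfTI file {path}: {e}") from e
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(data), tuple(float(z) for z in zooms),
                  np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
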