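"""Synthetic CT liver phantoms with paired 3-class label maps.

Each phantom emulates the statistical structure of an annotated abdominal CT:
an elliptical soft-tissue "body" against air (−1000 HU), a large ellipsoidal
"liver" of moderate intensity, and 0–3 hypodense spherical "tumors" fully
contained in the liver.  Per-region intensities are drawn voxelwise, lightly
Gaussian-smoothed so boundaries blur as in real CT, then corrupted with
additive noise.  Labels: 0 = background, 1 = liver, 2 = tumor.

Everything is a pure function of ``(config, seed)``, so downstream modules
are testable without any data download.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume, write_volume

__all__ = ["PhantomConfig", "make_phantom", "make_dataset"]

_MAX_PLACEMENT_TRIES = 200


@dataclass
class PhantomConfig:
    """Geometry and intensity model of one phantom.

    ``hu_*`` pairs are (mean, sd) in Hounsfield units.  Tumors are drawn
    hypodense relative to liver (mean ordering enforced), matching the
    contrast that windowing is meant to enhance.
    """

    shape: tuple = (32, 64, 64)
    liver_axes: tuple = (10.0, 18.0, 18.0)
    n_tumors: int = 2
    tumor_radius_range: tuple = (2.5, 5.0)
    hu_background: tuple = (-80.0, 20.0)
    hu_liver: tuple = (60.0, 10.0)
    hu_tumor: tuple = (25.0, 10.0)
    hu_air: float = -1000.0
    noise_sd: float = 5.0
    smooth_sigma: float = 1.0
    body_margin: float = 0.92
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 16, got {self.shape}")
        if not 0 <= self.n_tumors <= 3:
            raise ValueError(f"n_tumors must be in 0..3, got {self.n_tumors}")
        rmin, rmax = self.tumor_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError(f"bad tumor_radius_range {self.tumor_radius_range}")
        if rmax >= min(self.liver_axes):
            raise ValueError("max tumor radius must be smaller than the "
                             "smallest liver semi-axis")
        if self.hu_tumor[0] >= self.hu_liver[0]:
            raise ValueError("tumors must be hypodense: hu_tumor mean < hu_liver mean")


def _ellipsoid(shape, center, axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def make_phantom(config: PhantomConfig):
    """Generate one phantom.

    Returns
    -------
    (Volume, Volume)
        Image in HU and the aligned integer label map (values in {0, 1, 2}).
    """
    rng = np.random.default_rng(config.seed)
    D, H, W = config.shape

    # body: elliptical cylinder of soft tissue along the depth axis
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    by, bx = config.body_margin * H / 2.0, config.body_margin * W / 2.0
    gy, gx = np.ogrid[0:H, 0:W]
    body2d = ((gy - cy) / by) ** 2 + ((gx - cx) / bx) ** 2 <= 1.0
    body = np.broadcast_to(body2d, (D, H, W))

    # liver ellipsoid, jittered off-center but inside the body
    c0 = np.array([(D - 1) / 2.0, (H - 1) / 2.0, (W - 1) / 2.0])
    jitter = rng.uniform(-0.05, 0.05, size=3) * np.array([D, H, W])
    liver_center = c0 + jitter
    liver = _ellipsoid((D, H, W), liver_center, config.liver_axes)

    # tumors: spheres rejection-sampled until fully inside the liver
    tumor = np.zeros((D, H, W), dtype=bool)
    ax = np.asarray(config.liver_axes, dtype=float)
    for _ in range(config.n_tumors):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            r = rng.uniform(*config.tumor_radius_range)
            # sample center in the shrunken ellipsoid that guarantees the
            # whole sphere stays inside the liver surface
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform() ** (1 / 3)
            center = liver_center + u * rad * (ax - r)
            q = np.sum(((center - liver_center) / (ax - r)) ** 2)
            if q <= 1.0:
                tumor |= _ellipsoid((D, H, W), center, (r, r, r))
                break
        else:
            raise RuntimeError("could not place a tumor inside the liver")
    tumor &= liver  # guard against discretization at the surface

    labels = np.zeros((D, H, W), dtype=np.int16)
    labels[liver] = 1
    labels[tumor] = 2

    img = np.full((D, H, W), config.hu_air, dtype=np.float32)
    img[body] = rng.normal(*config.hu_background, size=int(body.sum()))
    img[liver] = rng.normal(*config.hu_liver, size=int(liver.sum()))
    img[tumor] = rng.normal(*config.hu_tumor, size=int(tumor.sum()))
    if config.smooth_sigma > 0:
        img = gaussian_filter(img, config.smooth_sigma)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = img.astype(np.float32)

    affine = np.eye(4)
    return Volume(img, (1.0, 1.0, 1.0), affine), Volume(labels, (1.0, 1.0, 1.0), affine)


def make_dataset(n: int, config: PhantomConfig, out_dir) -> dict:
    """Write ``n`` phantom image/label NIfTI pairs plus a JSON manifest.

    Case ``i`` uses seed ``config.seed + i``, so the manifest alone
    reproduces every case.  Returns the manifest dict.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    cases = []
    for i in range(n):
        cfg = PhantomConfig(**{**config.__dict__, "seed": config.seed + i})
        img, lab = make_phantom(cfg)
        img_path = os.path.join(out_dir, f"case_{i:03d}_image.nii.gz")
        lab_path = os.path.join(out_dir, f"case_{i:03d}_label.nii.gz")
        write_volume(img, img_path)
        write_volume(lab, lab_path)
        cases.append({"image": img_path, "label": lab_path, "seed": cfg.seed})
    manifest = {"n": n, "shape": list(config.shape), "cases": cases}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
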