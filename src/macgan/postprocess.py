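"""Connected-component cleanup of segmentation masks.

A human body contains exactly one liver, so disconnected fragments in a
liver mask are false positives.  The rule: find connected components, let
``x`` be the voxel count of the largest, and remove every component whose
count is strictly less than ``rate × x`` (ties survive).  Default rate 0.3,
26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ComponentFilterSpec", "keep_major_components", "postprocess_case"]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class ComponentFilterSpec:
    rate: float = 0.3
    connectivity: int = 26

    def __post_init__(self):
        if not 0.0 < self.rate <= 1.0:
            raise ValueError(f"rate must be in (0, 1], got {self.rate}")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")


def keep_major_components(mask, spec: ComponentFilterSpec = ComponentFilterSpec()):
    """Remove components with voxel count < rate × (largest component count).

    The largest component always survives; no voxel is ever added.  An empty
    mask passes through unchanged.
    """
    m = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(m.ndim, _STRUCTURES[spec.connectivity])
    labeled, n = ndimage.label(m, structure=structure)
    if n == 0:
        return np.zeros_like(m)
    counts = np.bincount(labeled.ravel())[1:]  # skip background
    threshold = spec.rate * counts.max()
    keep = np.flatnonzero(counts >= threshold) + 1  # strict removal: < threshold
    return np.isin(labeled, keep)


def postprocess_case(liver_prob, tumor_prob, threshold: float = 0.5,
                     spec: ComponentFilterSpec = ComponentFilterSpec()):
    """Compose per-class probabilities into a cleaned 3-class label map.

    The liver probability is binarized and component-filtered; the tumor
    probability is binarized and intersected with the surviving liver mask
    (tumors live inside the liver).  Output values ⊆ {0, 1, 2}.
    """
    liver_prob, tumor_prob = np.asarray(liver_prob), np.asarray(tumor_prob)
    if liver_prob.shape != tumor_prob.shape:
        raise ValueError(f"shape mismatch {liver_prob.shape} vs {tumor_prob.shape}")
    liver = keep_major_components(liver_prob >= threshold, spec)
    tumor = (tumor_prob >= threshold) & liver
    out = np.zeros(liver.shape, dtype=np.int16)
    out[liver] = 1
    out[tumor] = 2
    return out
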