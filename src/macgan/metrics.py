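"""Overlap and surface-distance metrics for 3-D binary masks.

Dice 2|S∩G|/(|S|+|G|) and Jaccard |S∩G|/|S∪G| are voxel-count overlaps.
HD95 is the maximum of the two directed 95th-percentile Euclidean surface
distances (robust Hausdorff); ASD is the symmetric mean of the directed mean
surface distances.  Surfaces are foreground voxels with at least one
background face-neighbor (6-neighborhood).  Distances are in mm when a
spacing is given, else voxel units.

Conventions for degenerate masks: if both masks are empty the prediction
perfectly matches an absent structure (dice = jaccard = 1, distances = 0);
if exactly one is empty, dice = jaccard = 0 and the distance metrics are
undefined (NaN by default, configurable sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

__all__ = ["dice", "jaccard", "surface_points", "hd95", "asd",
           "ClassMetrics", "MetricsReport", "evaluate_case"]


def _as_bool(mask, name):
    m = np.asarray(mask)
    out = m.astype(bool)
    if m.dtype != bool and not np.array_equal(m, out):
        raise ValueError(f"{name} must be binary")
    return out


def _check_pair(s, g):
    s, g = _as_bool(s, "S"), _as_bool(g, "G")
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {g.shape}")
    return s, g


def dice(s, g) -> float:
    """Dice coefficient; 1 = perfect overlap, 0 = disjoint."""
    s, g = _check_pair(s, g)
    ns, ng = int(s.sum()), int(g.sum())
    if ns + ng == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / (ns + ng)


def jaccard(s, g) -> float:
    """Jaccard index |S∩G|/|S∪G|."""
    s, g = _check_pair(s, g)
    union = int((s | g).sum())
    if union == 0:
        return 1.0
    return int((s & g).sum()) / union


def surface_points(mask) -> np.ndarray:
    """Coordinates [n, 3] of foreground voxels with a background face-neighbor."""
    m = _as_bool(mask, "mask")
    if not m.any():
        raise ValueError("surface of an empty mask is undefined")
    if m.ndim != 3:
        raise ValueError("expected a 3-D mask")
    inner = binary_erosion(m, structure=generate_binary_structure(3, 1),
                           border_value=0)
    return np.argwhere(m & ~inner)


def _directed_distances(p_from, p_to, spacing):
    sp = np.asarray(spacing, dtype=float)
    tree = cKDTree(p_to * sp)
    d, _ = tree.query(p_from * sp, k=1)
    return np.asarray(d, dtype=float)


def _surface_setup(s, g, spacing, undefined):
    s, g = _check_pair(s, g)
    es, eg = not s.any(), not g.any()
    if es and eg:
        return 0.0, None
    if es or eg:
        return float(undefined) if undefined is not None else float("nan"), None
    ps, pg = surface_points(s), surface_points(g)
    sp = (1.0, 1.0, 1.0) if spacing is None else spacing
    return None, (_directed_distances(ps, pg, sp), _directed_distances(pg, ps, sp))


def hd95(s, g, spacing=None, undefined=None) -> float:
    """Max of the two directed 95th-percentile surface distances.

    Percentiles use numpy's linear interpolation between order statistics.
    """
    early, dists = _surface_setup(s, g, spacing, undefined)
    if dists is None:
        return early
    d_sg, d_gs = dists
    return float(max(np.percentile(d_sg, 95), np.percentile(d_gs, 95)))


def asd(s, g, spacing=None, undefined=None) -> float:
    """Average symmetric surface distance: ½(mean d(S→G) + mean d(G→S))."""
    early, dists = _surface_setup(s, g, spacing, undefined)
    if dists is None:
        return early
    d_sg, d_gs = dists
    return float(0.5 * (d_sg.mean() + d_gs.mean()))


@dataclass
class ClassMetrics:
    dice: float
    jaccard: float
    hd95: float
    asd: float


@dataclass
class MetricsReport:
    """Per-class metrics for one prediction/reference pair of label maps."""

    liver: ClassMetrics
    tumor: ClassMetrics

    def as_row(self) -> dict:
        row = {}
        for cls in ("liver", "tumor"):
            cm = getattr(self, cls)
            for m in ("dice", "jaccard", "hd95", "asd"):
                row[f"{cls}_{m}"] = getattr(cm, m)
        return row


def evaluate_case(pred, ref, spacing=None, undefined=None) -> MetricsReport:
    """Evaluate a 3-class prediction against a reference.

    Liver = labels {1, 2} merged; tumor = label 2.
    """
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    out = {}
    for cls, sel in (("liver", lambda a: a >= 1), ("tumor", lambda a: a == 2)):
        s, g = sel(pred), sel(ref)
        out[cls] = ClassMetrics(dice(s, g), jaccard(s, g),
                                hd95(s, g, spacing, undefined),
                                asd(s, g, spacing, undefined))
    return MetricsReport(**out)
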