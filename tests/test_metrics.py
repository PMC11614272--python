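"""Overlap and surface-distance metrics against brute-force all-pairs oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from macgan import (asd, dice, evaluate_case, hd95, jaccard, surface_points)
from tests.conftest import random_mask


def brute_surface(mask):
    pts = []
    m = np.asarray(mask, bool)
    for idx in np.argwhere(m):
        for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)]:
            j = idx + off
            if np.any(j < 0) or np.any(j >= m.shape) or not m[tuple(j)]:
                pts.append(idx)
                break
    return np.array(pts)


def brute_hd95_asd(s, g, spacing=(1.0, 1.0, 1.0)):
    ps = brute_surface(s) * np.asarray(spacing)
    pg = brute_surface(g) * np.asarray(spacing)
    d = cdist(ps, pg)
    d_sg, d_gs = d.min(axis=1), d.min(axis=0)
    hd = max(np.percentile(d_sg, 95), np.percentile(d_gs, 95))
    a = 0.5 * (d_sg.mean() + d_gs.mean())
    hausdorff = max(d_sg.max(), d_gs.max())
    return hd, a, hausdorff


def test_dice_identical_and_disjoint():
    m = np.zeros((4, 4, 4), bool)
    m[1:3, 1:3, 1:3] = True
    assert dice(m, m) == 1.0
    other = np.zeros_like(m)
    other[0, 0, 0] = True
    assert dice(m, other) == 0.0


def test_dice_half_overlap_closed_form():
    s = np.zeros((2, 2, 2), bool)
    g = np.zeros((2, 2, 2), bool)
    s.ravel()[[0, 1, 2, 3]] = True
    g.ravel()[[2, 3, 4, 5]] = True
    assert dice(s, g) == pytest.approx(0.5)
    assert jaccard(s, g) == pytest.approx(1 / 3)


def test_jaccard_dice_identity(rng):
    for _ in range(20):
        s, g = random_mask(rng), random_mask(rng)
        d, j = dice(s, g), jaccard(s, g)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        assert j <= d + 1e-12


def test_surface_of_cube_and_single_voxel():
    cube = np.zeros((5, 5, 5), bool)
    cube[1:4, 1:4, 1:4] = True
    pts = surface_points(cube)
    assert len(pts) == 26            # all but the center voxel
    single = np.zeros((3, 3, 3), bool)
    single[1, 1, 1] = True
    np.testing.assert_array_equal(surface_points(single), [[1, 1, 1]])
    with pytest.raises(ValueError):
        surface_points(np.zeros((2, 2, 2), bool))


def test_hd95_asd_single_point_pairs():
    s = np.zeros((1, 1, 5), bool)
    g = np.zeros((1, 1, 5), bool)
    s[0, 0, 0] = True
    g[0, 0, 3] = True
    assert hd95(s, g) == pytest.approx(3.0)
    assert asd(s, g) == pytest.approx(3.0)
    assert hd95(s, s) == 0.0 and asd(s, s) == 0.0


def test_distance_metrics_match_brute_force_oracle(rng):
    for _ in range(100):
        s = random_mask(rng, (8, 8, 8), p=0.35)
        g = random_mask(rng, (8, 8, 8), p=0.35)
        if not s.any() or not g.any():
            continue
        ref_hd, ref_asd, ref_haus = brute_hd95_asd(s, g)
        assert hd95(s, g) == pytest.approx(ref_hd, abs=1e-9)
        assert asd(s, g) == pytest.approx(ref_asd, abs=1e-9)
        # ASD never exceeds the exact Hausdorff distance
        assert asd(s, g) <= ref_haus + 1e-9


def test_spacing_scales_distances():
    s = np.zeros((1, 1, 5), bool)
    g = np.zeros((1, 1, 5), bool)
    s[0, 0, 0] = True
    g[0, 0, 3] = True
    assert hd95(s, g, spacing=(1.0, 1.0, 0.5)) == pytest.approx(1.5)
    assert asd(s, g, spacing=(1.0, 1.0, 2.0)) == pytest.approx(6.0)


def test_symmetry_and_translation_invariance(rng):
    for _ in range(10):
        s = random_mask(rng, (7, 7, 7))
        g = random_mask(rng, (7, 7, 7))
        if not s.any() or not g.any():
            continue
        assert dice(s, g) == dice(g, s)
        assert jaccard(s, g) == jaccard(g, s)
        assert hd95(s, g) == pytest.approx(hd95(g, s), abs=1e-12)
        assert asd(s, g) == pytest.approx(asd(g, s), abs=1e-12)
        # shift both masks by the same offset inside a larger canvas
        S = np.zeros((12, 12, 12), bool)
        G = np.zeros((12, 12, 12), bool)
        S[2:9, 3:10, 1:8] = s
        G[2:9, 3:10, 1:8] = g
        S2 = np.roll(S, (2, 1, 3), axis=(0, 1, 2))
        G2 = np.roll(G, (2, 1, 3), axis=(0, 1, 2))
        assert dice(S, G) == dice(S2, G2)
        assert hd95(S, G) == pytest.approx(hd95(S2, G2), abs=1e-12)
        assert asd(S, G) == pytest.approx(asd(S2, G2), abs=1e-12)


def test_empty_mask_conventions():
    e = np.zeros((3, 3, 3), bool)
    m = ~e
    assert dice(e, e) == 1.0 and jaccard(e, e) == 1.0
    assert hd95(e, e) == 0.0 and asd(e, e) == 0.0
    assert dice(m, e) == 0.0
    assert np.isnan(hd95(m, e))
    assert hd95(m, e, undefined=999.0) == 999.0


def test_evaluate_case_classes_and_identity(small_phantom):
    _, lab = small_phantom
    report = evaluate_case(lab.data, lab.data)
    for cls in (report.liver, report.tumor):
        assert cls.dice == 1.0 and cls.jaccard == 1.0
        assert cls.hd95 == 0.0 and cls.asd == 0.0
    # remove the tumor from the prediction → tumor dice 0, liver unchanged
    pred = np.where(lab.data == 2, 1, lab.data)
    report = evaluate_case(pred, lab.data)
    assert report.tumor.dice == 0.0
    assert report.liver.dice == 1.0
    row = report.as_row()
    assert len(row) == 8
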