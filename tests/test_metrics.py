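"""Metric suite: hand-computed examples plus brute-force oracles."""
import numpy as np
import pytest

from hippounet.errors import DegenerateInputError
from hippounet.grids import LabelMap
from hippounet.metrics import (
    compactness,
    compactness_score,
    dice,
    evaluate_pair,
    hd95,
    precision_recall,
    surface_area,
    volume_similarity,
)
from conftest import random_mask

# ---------------------------------------------------------------- oracles


def brute_dice(y, yt):
    inter = np.sum(y & yt)
    return 2 * inter / (y.sum() + yt.sum())


def brute_surface_voxels(m):
    """Voxels of m with at least one 6-neighbour outside m (or on the border),
    matching surface extraction by connectivity-1 erosion."""
    out = np.zeros_like(m)
    coords = np.argwhere(m)
    for c in coords:
        on_surface = False
        for ax in range(m.ndim):
            for d in (-1, 1):
                n = c.copy()
                n[ax] += d
                if (n < 0).any() or (n >= np.array(m.shape)).any() or not m[tuple(n)]:
                    on_surface = True
        if on_surface:
            out[tuple(c)] = True
    return out


def brute_hd95(y, yt, spacing):
    """All-pairs surface distances, pooled 95th percentile."""
    sy = np.argwhere(brute_surface_voxels(y)) * np.asarray(spacing)
    st = np.argwhere(brute_surface_voxels(yt)) * np.asarray(spacing)
    d_yt = [min(np.linalg.norm(p - q) for q in st) for p in sy]
    d_ty = [min(np.linalg.norm(q - p) for p in sy) for q in st]
    return float(np.percentile(np.hstack((d_yt, d_ty)), 95))


def brute_surface_area(m, spacing):
    dx, dy, dz = spacing
    areas = (dy * dz, dx * dz, dx * dy)
    total = 0.0
    for c in np.argwhere(m):
        for ax in range(3):
            for d in (-1, 1):
                n = c.copy()
                n[ax] += d
                if (n < 0).any() or (n >= np.array(m.shape)).any() or not m[tuple(n)]:
                    total += areas[ax]
    return total


# ---------------------------------------------------------------- examples


def test_dice_examples():
    y = np.zeros((5, 5, 1), dtype=bool)
    yt = np.zeros_like(y)
    y[0:3, 0:3] = True  # 3x3 square
    yt[0:2, 0:3] = True  # overlapping 2x3 rectangle
    assert dice(yt, y) == pytest.approx(2 * 6 / (9 + 6))
    assert dice(y, y) == 1.0
    z = np.zeros_like(y)
    z[4, 4] = True
    assert dice(z, y) == 0.0
    with pytest.raises(DegenerateInputError):
        dice(y, np.zeros_like(y))


def test_hd95_shift_scales_with_spacing():
    base = np.zeros((12, 12, 4), dtype=bool)
    base[2:10, 2:10, 1:3] = True
    shifted = np.roll(base, 1, axis=0)
    for sp in ((0.16, 0.16, 0.16), (0.5, 0.5, 0.5)):
        assert hd95(shifted, base, sp) == pytest.approx(sp[0])
    assert hd95(base, base, (0.16, 0.16, 0.16)) == 0.0


def test_hd95_anisotropic_spacing_respected():
    a = np.zeros((6, 6, 6), dtype=bool)
    b = np.zeros_like(a)
    a[2, 2, 2] = True
    b[2, 2, 3] = True  # one step along z
    assert hd95(a, b, (0.15, 0.15, 0.5)) == pytest.approx(0.5)


def test_volume_similarity_examples():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros_like(a)
    a[:2] = True
    b[2:] = True  # equal volumes, disjoint
    assert volume_similarity(a, b) == 1.0
    yt = np.zeros_like(a)
    y = np.zeros_like(a)
    yt.ravel()[:10] = True
    y.ravel()[:8] = True
    assert volume_similarity(y, yt) == pytest.approx(1 - 2 / 18)
    assert volume_similarity(np.zeros_like(a), yt) == 0.0


def test_compactness_cube_vs_bar_face_counts():
    # 2x2x2 cube: 24 exposed faces; 1x1x8 bar: 34 faces (unit spacing)
    cube = np.zeros((10, 10, 10), dtype=bool)
    cube[1:3, 1:3, 1:3] = True
    bar = np.zeros_like(cube)
    bar[1, 1, 1:9] = True
    sp = (1.0, 1.0, 1.0)
    assert surface_area(cube, sp) == 24
    assert surface_area(bar, sp) == 34
    c_cube = 24**1.5 / 8
    c_bar = 34**1.5 / 8
    expected = 1 - 2 * abs(c_cube - c_bar) / (c_cube + c_bar)
    assert compactness_score(cube, bar, sp) == pytest.approx(expected)
    assert compactness_score(cube, cube, sp) == 1.0
    # translation invariance
    assert compactness(np.roll(cube, 3, axis=2), sp) == compactness(cube, sp)


def test_precision_recall_containment():
    yt = np.zeros((4, 4, 4), dtype=bool)
    yt.ravel()[:8] = True
    y = np.zeros_like(yt)
    y.ravel()[:16] = True  # superset, twice the size
    assert precision_recall(y, yt) == (0.5, 1.0)
    assert precision_recall(yt, y) == (1.0, 0.5)
    assert precision_recall(yt, yt) == (1.0, 1.0)


@pytest.mark.parametrize("seed", range(6))
def test_metrics_match_bruteforce_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(5, 12, size=3))
    spacing = tuple(rng.uniform(0.1, 0.6, size=3))
    y = random_mask(rng, shape)
    yt = random_mask(rng, shape)
    assert dice(y, yt) == pytest.approx(brute_dice(y, yt))
    assert hd95(y, yt, spacing) == pytest.approx(brute_hd95(y, yt, spacing), abs=1e-9)
    assert surface_area(y, spacing) == pytest.approx(brute_surface_area(y, spacing))
    p, r = precision_recall(y, yt)
    assert p == pytest.approx(np.sum(y & yt) / y.sum())
    assert r == pytest.approx(np.sum(y & yt) / yt.sum())


@pytest.mark.parametrize("seed", range(4))
def test_metric_invariants(seed):
    rng = np.random.default_rng(100 + seed)
    shape = (9, 9, 9)
    y = random_mask(rng, shape)
    yt = random_mask(rng, shape)
    sp = (0.2, 0.3, 0.4)
    # D <= VS since |intersection| <= min(|Y|,|Yt|)
    assert dice(y, yt) <= volume_similarity(y, yt) + 1e-12
    # symmetries
    assert dice(y, yt) == pytest.approx(dice(yt, y))
    assert volume_similarity(y, yt) == pytest.approx(volume_similarity(yt, y))
    assert compactness_score(y, yt, sp) == pytest.approx(compactness_score(yt, y, sp))
    assert hd95(y, yt, sp) == pytest.approx(hd95(yt, y, sp))
    p, r = precision_recall(y, yt)
    p2, r2 = precision_recall(yt, y)
    assert (p, r) == pytest.approx((r2, p2))


def test_evaluate_pair_perfect_and_partial(sham_phantom):
    _, labels = sham_phantom
    rep = evaluate_pair(labels, labels)
    for roi in ("ipsi", "contra"):
        assert rep.per_roi[roi]["dice"] == 1.0
        assert rep.per_roi[roi]["hd95"] == 0.0
        assert rep.per_roi[roi]["vs"] == 1.0
        assert rep.per_roi[roi]["cs"] == 1.0
        assert rep.per_roi[roi]["precision"] == 1.0
        assert rep.per_roi[roi]["recall"] == 1.0
        assert rep.volumes_mm3[roi]["pred"] == rep.volumes_mm3[roi]["truth"] > 0
    # D = 2PR/(P+R) identity on a corrupted prediction
    rng = np.random.default_rng(0)
    lab = labels.labels.copy()
    flip = rng.random(lab.shape) < 0.01
    lab[flip] = 0
    pred = LabelMap(labels=lab, brain=labels.brain, spacing=labels.spacing)
    rep = evaluate_pair(pred, labels)
    for roi in ("ipsi", "contra"):
        p, r, d = (rep.per_roi[roi][k] for k in ("precision", "recall", "dice"))
        assert d == pytest.approx(2 * p * r / (p + r), abs=1e-9)


def test_evaluate_pair_missing_class_isolated(sham_phantom):
    _, labels = sham_phantom
    lab = labels.labels.copy()
    lab[lab == 2] = 0  # drop contralateral prediction
    pred = LabelMap(labels=lab, brain=labels.brain, spacing=labels.spacing)
    rep = evaluate_pair(pred, labels)
    assert rep.per_roi["contra"]["hd95"] is None
    assert rep.per_roi["contra"]["precision"] is None
    assert rep.per_roi["contra"]["recall"] == 0.0
    assert rep.per_roi["ipsi"]["dice"] == 1.0
    assert "contra" in rep.reasons and rep.reasons["contra"]
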