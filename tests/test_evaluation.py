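"""Evaluation operations against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stwarp.deform import AffineTransform
from stwarp.evaluation import (RegionComposition, composition_distance,
                               cosine_similarity, cpm_log_normalize,
                               expand_region_knn, grid_aggregate,
                               landmark_rmse, matched_mask,
                               pseudospot_aggregate, random_region,
                               region_entropy)
from stwarp.lddmm import landmark_affine
from stwarp.points import PointSet


# ---------------------------------------------------------------------------
# landmark RMSE

def test_rmse_zero_for_exact_map():
    pts = np.array([[0.0, 0.0], [5.0, 5.0]])
    assert landmark_rmse(None, pts, pts) == 0.0


def test_rmse_three_four_five():
    assert landmark_rmse(None, [[0.0, 0.0]], [[3.0, 4.0]]) == pytest.approx(5.0)


def test_rmse_matches_per_pair_oracle(rng):
    aff = AffineTransform(np.eye(2) + 0.1 * rng.standard_normal((2, 2)),
                          rng.uniform(-10, 10, 2))
    pI = rng.uniform(0, 100, (9, 2))
    pJ = rng.uniform(0, 100, (9, 2))
    oracle = np.sqrt(np.mean([np.sum((aff.apply(pI[i:i + 1])[0] - pJ[i]) ** 2)
                              for i in range(9)]))
    assert landmark_rmse(aff, pI, pJ) == pytest.approx(oracle, rel=1e-12)


def test_landmark_affine_never_worse_than_identity(rng):
    for _ in range(5):
        pI = rng.uniform(0, 500, (8, 2))
        pJ = pI + rng.normal(0, 40, (8, 2))
        aff, _ = landmark_affine(pI, pJ)
        assert landmark_rmse(aff, pI, pJ) <= landmark_rmse(None, pI, pJ) + 1e-9


# ---------------------------------------------------------------------------
# aggregation

def test_grid_aggregate_single_cell():
    cells = PointSet([130.0], [70.0], feature_matrix=[[5.0]])
    keys, counts, centers = grid_aggregate(cells, 200.0, origin=(0.0, 0.0))
    assert keys.shape == (1, 2) and counts[0, 0] == 5.0
    np.testing.assert_array_equal(keys[0], [0, 0])
    np.testing.assert_array_equal(centers[0], [100.0, 100.0])


def test_grid_aggregate_conserves_counts(rng):
    feats = rng.integers(0, 10, size=(200, 6)).astype(float)
    cells = PointSet(rng.uniform(0, 1000, 200), rng.uniform(0, 1000, 200),
                     feature_matrix=feats)
    _, counts, _ = grid_aggregate(cells, 200.0)
    np.testing.assert_allclose(counts.sum(axis=0), feats.sum(axis=0), rtol=1e-12)


def test_grid_aggregate_matches_floor_division_oracle(rng):
    feats = rng.integers(0, 5, size=(50, 2)).astype(float)
    xs, ys = rng.uniform(-300, 300, 50), rng.uniform(-300, 300, 50)
    cells = PointSet(xs, ys, feature_matrix=feats)
    origin = np.array([-300.0, -300.0])
    keys, counts, _ = grid_aggregate(cells, 150.0, origin)
    lookup = {tuple(k): counts[i] for i, k in enumerate(keys)}
    oracle = {}
    for k in range(50):
        key = (int(np.floor((xs[k] - origin[0]) / 150.0)),
               int(np.floor((ys[k] - origin[1]) / 150.0)))
        oracle.setdefault(key, np.zeros(2))
        oracle[key] += feats[k]
    assert set(lookup) == set(oracle)
    for key in oracle:
        np.testing.assert_allclose(lookup[key], oracle[key])


def test_pseudospot_membership_boundary():
    cells = PointSet([0.0, 0.0], [49.999, 50.001], feature_matrix=[[1.0], [1.0]])
    counts = pseudospot_aggregate(cells, [[0.0, 0.0]], radius=50.0)
    assert counts[0, 0] == 1.0  # strict inequality: only the inner cell


def test_pseudospot_matches_distance_matrix_oracle(rng):
    feats = rng.integers(0, 4, size=(80, 3)).astype(float)
    cells = PointSet(rng.uniform(0, 400, 80), rng.uniform(0, 400, 80),
                     feature_matrix=feats)
    centers = rng.uniform(0, 400, (12, 2))
    out = pseudospot_aggregate(cells, centers, radius=60.0)
    dists = np.linalg.norm(cells.coords[None] - centers[:, None], axis=2)
    oracle = np.stack([feats[dists[s] < 60.0].sum(axis=0) for s in range(12)])
    np.testing.assert_allclose(out, oracle)


def test_cpm_log_normalize_example():
    X = np.array([[1.0, 1.0, 2.0]])
    norm, zero = cpm_log_normalize(X)
    np.testing.assert_allclose(norm[0], np.log10(np.array([250000, 250000, 500000]) + 1))
    assert not zero[0]


def test_cpm_zero_rows_flagged():
    norm, zero = cpm_log_normalize(np.array([[0.0, 0.0], [1.0, 3.0]]))
    np.testing.assert_array_equal(norm[0], 0.0)
    assert list(zero) == [True, False]
    # nonzero rows scale to one million before the log
    assert (10 ** norm[1] - 1).sum() == pytest.approx(1e6, rel=1e-9)


def test_cpm_rejects_negative():
    with pytest.raises(ValueError):
        cpm_log_normalize(np.array([[-1.0, 2.0]]))


# ---------------------------------------------------------------------------
# cosine similarity

def test_cosine_examples():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
        32.0 / (np.sqrt(14.0) * np.sqrt(77.0)))
    assert np.isnan(cosine_similarity([0.0, 0.0], [0.0, 0.0]))
    with pytest.raises(ValueError):
        cosine_similarity([1.0], [1.0, 2.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=8),
       st.floats(0.1, 50.0))
def test_cosine_scale_invariant_and_bounded(u, c):
    u = np.asarray(u)
    if np.linalg.norm(u) == 0:
        return
    assert cosine_similarity(u, c * u) == pytest.approx(1.0, abs=1e-9)
    v = np.ones_like(u)
    s = cosine_similarity(u, v)
    assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# matched mask

def test_matched_mask_thresholds():
    W = np.array([[0.0, 0.3], [0.9, 1.0]])
    assert matched_mask(W, 0.0).sum() == 3  # strictly positive posteriors
    assert matched_mask(W, 1.0).sum() == 0


def test_matched_mask_cell_membership():
    W = np.zeros((4, 4))
    W[2, 1] = 0.95
    rows = 10.0 * (0.5 + np.arange(4))
    cols = 10.0 * (0.5 + np.arange(4))
    cells = PointSet([15.0, 35.0, -50.0], [25.0, 25.0, 25.0])
    mask, keep = matched_mask(W, 0.85, grid=(rows, cols), points=cells)
    assert list(keep) == [True, False, False]


# ---------------------------------------------------------------------------
# regions

def test_entropy_closed_forms():
    assert region_entropy(np.array([2, 2, 2])) == pytest.approx(0.0)
    assert region_entropy(np.array([0, 1])) == pytest.approx(np.log(2.0))
    assert region_entropy(np.full(6, 1.0 / 6)) == pytest.approx(np.log(6.0))
    labels = np.repeat(np.arange(5), 10)
    assert region_entropy(labels) == pytest.approx(np.log(5.0))


def test_random_region_deterministic_and_exact(rng):
    cells = PointSet(rng.uniform(0, 100, 60), rng.uniform(0, 100, 60))
    r1 = random_region(cells, 15, seed=7)
    r2 = random_region(cells, 15, seed=7)
    np.testing.assert_array_equal(r1, r2)
    assert len(r1) == 15
    assert len(random_region(cells, 60, seed=0)) == 60
    with pytest.raises(ValueError):
        random_region(cells, 61, seed=0)


def test_random_region_matches_full_sort_oracle(rng):
    cells = PointSet(rng.uniform(0, 100, 40), rng.uniform(0, 100, 40))
    idx = random_region(cells, 10, seed=3)
    center_rng = np.random.default_rng(3)
    center = np.array([center_rng.uniform(cells.x.min(), cells.x.max()),
                       center_rng.uniform(cells.y.min(), cells.y.max())])
    d = np.linalg.norm(cells.coords - center, axis=1)
    assert d[idx].max() <= np.sort(d)[9] + 1e-12


def test_expand_region_knn_properties(rng):
    cells = PointSet(rng.uniform(0, 200, 100), rng.uniform(0, 200, 100))
    region = np.arange(10)
    np.testing.assert_array_equal(expand_region_knn(region, cells, k=0), region)
    expanded = expand_region_knn(region, cells, k=5)
    assert set(region) <= set(expanded)
    assert len(expanded) >= len(region)
    # brute-force oracle: union of each member's 5 nearest cells
    oracle = set(region)
    for m in region:
        d = np.linalg.norm(cells.coords - cells.coords[m], axis=1)
        oracle |= set(np.argsort(d, kind="stable")[:6])  # includes self
    assert set(expanded) == oracle


def test_entropy_rises_when_expansion_crosses_boundary(rng):
    # pure region surrounded by a different type: expansion must raise entropy;
    # surrounded by the same type: entropy unchanged
    inner = rng.normal(0, 10, (50, 2))
    outer_t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    outer = 60.0 * np.column_stack([np.cos(outer_t), np.sin(outer_t)])
    coords = np.vstack([inner, outer])
    labels_mixed = np.array([0] * 50 + [1] * 100)
    labels_same = np.zeros(150, dtype=int)
    cells = PointSet(coords[:, 0], coords[:, 1])
    region = np.arange(50)
    # k exceeds the region's own size, so expansion must cross the boundary
    expanded = expand_region_knn(region, cells, k=60)
    e0 = region_entropy(labels_mixed[region])
    e1 = region_entropy(labels_mixed[expanded])
    assert e1 > e0
    assert region_entropy(labels_same[expanded]) == region_entropy(labels_same[region])


def test_composition_distance():
    a = RegionComposition("r", 10, [1.0, 0.0])
    b = RegionComposition("r", 12, [0.0, 1.0])
    assert composition_distance(a, b) == pytest.approx(np.sqrt(2.0))
    assert composition_distance(a, a) == 0.0
    c = RegionComposition.from_labels("r", [0, 0, 1, 1], n_types=2)
    np.testing.assert_allclose(c.proportions, [0.5, 0.5])
    with pytest.raises(ValueError):
        RegionComposition("bad", 5, [0.5, 0.4])
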