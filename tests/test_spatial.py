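import numpy as np
import pytest

from milfoilsdm import (
    assign_blocks,
    autocovariate,
    build_weights,
    morans_i,
    pair_correlation,
)
from .oracles import autocovariate_double_loop, morans_i_double_sum


def test_collinear_band_weights_row_standardize():
    w = build_weights([(0, 0), (1, 0), (2, 0)], radius=1.5)
    W = w.row_standardized.toarray()
    # middle point: two neighbors at distance 1 -> equal weights 0.5
    assert W[1, 0] == pytest.approx(0.5)
    assert W[1, 2] == pytest.approx(0.5)
    assert W[1, 1] == 0


def test_auto_radius_is_max_nearest_neighbor_distance():
    w = build_weights([(0, 0), (1, 0), (2, 0)], radius="auto")
    assert w.radius == pytest.approx(1.0, rel=1e-6)


def test_duplicate_coordinates_rejected_with_jitter_hint():
    with pytest.raises(ValueError, match="jitter"):
        build_weights([(0, 0), (0, 0), (1, 1)])


def test_weights_match_brute_force_inverse_distance(rng):
    pts = rng.uniform(0, 10, (50, 2))
    w = build_weights(pts, radius=3.0)
    W = w.W.toarray()
    for i in range(50):
        for j in range(50):
            d = float(np.hypot(*(pts[i] - pts[j])))
            expected = 1.0 / d if (i != j and d <= 3.0) else 0.0
            assert W[i, j] == pytest.approx(expected, abs=1e-12)


def test_autocovariate_equals_neighbor_mean_special_cases():
    # all neighbors have response 1 -> autocovariate 1
    w = build_weights([(0, 0), (1, 0), (0, 1), (1, 1)], radius=2.0)
    assert autocovariate(w, [1, 1, 1, 1]) == pytest.approx([1, 1, 1, 1])
    # two equidistant neighbors with responses 0 and 1 -> 0.5
    w3 = build_weights([(0, 0), (1, 0), (-1, 0)], radius=1.5)
    assert autocovariate(w3, [9.0, 0.0, 1.0])[0] == pytest.approx(0.5)


def test_autocovariate_matches_double_loop_oracle(rng):
    pts = rng.uniform(0, 5, (20, 2))
    y = rng.random(20)
    w = build_weights(pts, radius="auto")
    expected = autocovariate_double_loop(pts, y, w.radius)
    assert np.max(np.abs(autocovariate(w, y) - expected)) < 1e-12


def test_autocovariate_translation_invariant_and_linear(rng):
    pts = rng.uniform(0, 5, (30, 2))
    y = rng.random(30)
    ac = autocovariate(build_weights(pts, radius=2.0), y)
    shifted = autocovariate(build_weights(pts + [100.0, -40.0], radius=2.0), y)
    assert np.allclose(ac, shifted, atol=1e-9)
    scaled = autocovariate(build_weights(pts, radius=2.0), 3.0 * y + 1.0)
    assert np.allclose(scaled, 3.0 * ac + 1.0, atol=1e-9)


def test_morans_i_negative_on_checkerboard():
    xx, yy = np.meshgrid(np.arange(4), np.arange(4))
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    values = (xx + yy).ravel() % 2
    w = build_weights(pts, radius=1.0)  # rook adjacency
    res = morans_i(w, values, n_perm=0)
    assert res.I < 0


def test_morans_i_matches_hand_double_sum():
    pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
    w = build_weights(pts, radius=1.0)  # adjacent neighbors, weight 1
    values = [1.0, 1.0, 0.0, 0.0]
    expected = morans_i_double_sum(w.row_standardized.toarray(), values)
    res = morans_i(w, values, n_perm=0)
    assert res.I == pytest.approx(expected, abs=1e-12)


def test_morans_i_matches_oracle_on_random_fixture(rng):
    pts = rng.uniform(0, 10, (40, 2))
    vals = rng.standard_normal(40)
    w = build_weights(pts, radius="auto")
    expected = morans_i_double_sum(w.row_standardized.toarray(), vals)
    assert morans_i(w, vals, n_perm=0).I == pytest.approx(expected, abs=1e-12)


def test_morans_i_rejects_constant_values():
    w = build_weights([(0, 0), (1, 0), (2, 0)], radius=1.5)
    with pytest.raises(ValueError, match="constant"):
        morans_i(w, [2.0, 2.0, 2.0])


def test_pair_correlation_near_one_for_poisson(rng):
    pts = rng.uniform(0, [600, 560], (2000, 2))
    r = np.arange(5.0, 31.0, 5.0)
    g = pair_correlation(pts, r, ring_width=5.0, window=(600, 560))
    assert np.abs(g.mean() - 1.0) < 0.1


def test_pair_correlation_detects_thomas_clustering(rng):
    parents = rng.uniform(0, [600, 560], (50, 2))
    sigma = 10.0
    idx = rng.integers(50, size=2000)
    pts = parents[idx] + rng.normal(scale=sigma, size=(2000, 2))
    g = pair_correlation(pts, np.array([5.0, 10.0, 15.0]), ring_width=5.0,
                         window=(600, 560))
    assert (g > 1.0).all()  # clustered at r < 2*sigma


def test_pair_correlation_two_points_single_annulus():
    with pytest.warns(UserWarning):
        g = pair_correlation([(0, 0), (3, 0)], np.array([1.0, 3.0, 5.0]),
                             ring_width=1.0, window=(10, 10))
    assert g[0] == 0 and g[2] == 0 and g[1] > 0


def test_assign_blocks_requires_enough_occupied_blocks(rng):
    pts = rng.uniform(0, 5, (20, 2))
    with pytest.raises(ValueError, match="occupied"):
        assign_blocks(pts, block_side=100.0, k_folds=2, rng=rng)


def test_assign_blocks_keeps_separated_clusters_whole(rng):
    a = rng.normal([0, 0], 1.0, (30, 2))
    b = rng.normal([100, 100], 1.0, (30, 2))
    pts = np.vstack([a, b])
    blocks = assign_blocks(pts, block_side=20.0, k_folds=2, rng=rng)
    folds = blocks.folds
    assert len(set(folds[:30])) == 1
    assert len(set(folds[30:])) == 1
    assert folds[0] != folds[30]


def test_assign_blocks_partition_and_balance(rng):
    pts = rng.uniform(0, 100, (300, 2))
    blocks = assign_blocks(pts, block_side=10.0, k_folds=5, rng=rng)
    df = blocks.df
    assert sorted(df["fold"].unique()) == [1, 2, 3, 4, 5]
    # all lakes of a block share one fold
    assert (df.groupby("block")["fold"].nunique() == 1).all()
    sizes = df["fold"].value_counts()
    max_occ = df["block"].value_counts().max()
    assert sizes.max() - sizes.min() <= max_occ


def test_weights_and_blocks_export_csv(tmp_path, rng):
    import pandas as pd

    pts = rng.uniform(0, 10, (20, 2))
    w = build_weights(pts, radius="auto")
    w.to_triplet_csv(tmp_path / "w.csv")
    trip = pd.read_csv(tmp_path / "w.csv")
    assert set(trip.columns) == {"i", "j", "w"}
    assert (trip["w"] > 0).all()
    assert len(trip) == w.W.nnz

    blocks = assign_blocks(pts, block_side=2.0, k_folds=3, rng=rng,
                           ids=[f"l{i}" for i in range(20)])
    blocks.to_csv(tmp_path / "b.csv")
    back = pd.read_csv(tmp_path / "b.csv")
    assert list(back.columns) == ["id", "block", "fold"]
    assert len(back) == 20
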