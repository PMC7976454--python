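"""Sparse change features, SGD ridge fit vs closed form, display rescaling."""

import numpy as np
import pytest
from scipy import sparse

from wmhmap import (LesionMask, build_change_features, encode_response,
                    evolution_mask, fit_sgd_ridge, rescale_for_display)
from wmhmap.association import ChangeFeatureMatrix, fit_voxelwise_inverse
from wmhmap.volumetrics import CODE_PROGRESSED, CODE_REGRESSED


def _evolution_maps(rng, n=6, dims=(8, 8, 8)):
    maps = {}
    for i in range(n):
        b = (rng.random(dims) > 0.5).astype(np.uint8)
        f = (rng.random(dims) > 0.5).astype(np.uint8)
        maps[f"s{i}"] = evolution_mask(LesionMask(b, (1, 1, 1)),
                                       LesionMask(f, (1, 1, 1)))
    return maps


def test_no_change_gives_zero_row(rng):
    b = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
    emap = evolution_mask(LesionMask(b, (1, 1, 1)), LesionMask(b, (1, 1, 1)))
    feats = build_change_features({"s0": emap}, np.ones((6, 6, 6), dtype=bool))
    assert feats.values.nnz == 0


def test_column_sums_match_volumetric_counts(rng):
    """Cross-module audit: column sums equal progressed minus regressed counts."""
    maps = _evolution_maps(rng)
    mask = np.ones((8, 8, 8), dtype=bool)
    feats = build_change_features(maps, mask)
    col_sums = np.asarray(feats.values.sum(axis=0)).ravel()
    prog = sum((m.codes == CODE_PROGRESSED).astype(int) for m in maps.values())
    regr = sum((m.codes == CODE_REGRESSED).astype(int) for m in maps.values())
    assert np.array_equal(feats.to_grid(col_sums), prog - regr)


def test_constant_progressed_column(rng):
    maps = _evolution_maps(rng)
    for m in maps.values():
        m.codes[0, 0, 0] = CODE_PROGRESSED
    feats = build_change_features(maps, np.ones((8, 8, 8), dtype=bool))
    col = np.flatnonzero((feats.voxel_index == [0, 0, 0]).all(axis=1))[0]
    assert np.asarray(feats.values[:, col].todense()).ravel().tolist() \
        == [1] * len(maps)


def test_feature_congruence_error(rng):
    maps = _evolution_maps(rng)
    with pytest.raises(ValueError, match="congruent"):
        build_change_features(maps, np.ones((9, 9, 9), dtype=bool))


def _dense_features(X):
    n, p = X.shape
    vi = np.argwhere(np.ones((p, 1, 1), dtype=bool))
    return ChangeFeatureMatrix([f"s{i}" for i in range(n)], vi,
                               sparse.csr_matrix(X), (p, 1, 1), (1.0, 1.0, 1.0))


def test_sgd_matches_closed_form_ridge():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 15))
    y = X @ rng.normal(size=15) + 0.1 * rng.normal(size=40)
    lam = 1.0 / 47.0
    oracle = np.linalg.solve(X.T @ X + 40 * lam * np.eye(15), X.T @ y)
    amap = fit_sgd_ridge(_dense_features(X), y, lam=lam, loss="squared",
                         epochs=6000, seed=0, fit_intercept=False)
    w = amap.weights.reshape(-1)
    assert np.linalg.norm(w - oracle) / np.linalg.norm(oracle) < 1e-3


def test_sgd_seed_determinism():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 10))
    y = rng.normal(size=20)
    a = fit_sgd_ridge(_dense_features(X), y, epochs=20, seed=9)
    b = fit_sgd_ridge(_dense_features(X), y, epochs=20, seed=9)
    assert np.array_equal(a.weights, b.weights)
    assert a.intercept == b.intercept


def test_sgd_large_lambda_zeroes_weights():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 8))
    y = rng.normal(size=30) + 3.0
    amap = fit_sgd_ridge(_dense_features(X), y, lam=1e9, loss="squared", epochs=50)
    assert np.abs(amap.weights).max() < 1e-6


def test_sgd_weight_norm_shrinks_with_lambda():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 10))
    y = X @ rng.normal(size=10)
    norms = [np.linalg.norm(
        fit_sgd_ridge(_dense_features(X), y, lam=lam, loss="squared",
                      epochs=500, seed=0).weights)
        for lam in (0.01, 0.1, 1.0, 10.0)]
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_sgd_input_validation():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 4))
    with pytest.raises(ValueError, match="response length"):
        fit_sgd_ridge(_dense_features(X), np.zeros(7))
    with pytest.raises(ValueError, match="finite"):
        fit_sgd_ridge(_dense_features(X), np.full(10, np.nan))
    with pytest.raises(ValueError, match="lambda"):
        fit_sgd_ridge(_dense_features(X), np.zeros(10), lam=-1.0)


def test_sign_split_reconstruction():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(25, 12))
    y = X @ rng.normal(size=12)
    amap = fit_sgd_ridge(_dense_features(X), y, epochs=100, seed=0)
    assert np.array_equal(amap.positive_map - amap.negative_map, amap.weights)
    assert (amap.positive_map >= 0).all() and (amap.negative_map >= 0).all()


def test_encode_response(small_cohort):
    t = small_cohort.table
    y = encode_response(t, mode="location_code")
    no_rssi = t["rssi_location_codes"].map(len) == 0
    assert (y[no_rssi.to_numpy()] == 0).all()
    region = "centrum semiovale"
    ind = encode_response(t, mode="location_indicator", region=region)
    expected = t["rssi_location_codes"].map(
        lambda c: 1.0 if c and c[0][0] == region else 0.0).to_numpy()
    assert np.array_equal(ind, expected)


def test_encode_degenerate_response_raises(small_cohort):
    t = small_cohort.table.copy()
    t["rssi_location_codes"] = [[("thalamus", "left")]] * len(t)
    t["rssi_volume_ml"] = 1.0
    with pytest.raises(ValueError, match="degenerate"):
        encode_response(t, mode="location_indicator", region="thalamus")


def test_inverse_orientation_recovers_sign():
    rng = np.random.default_rng(9)
    n, p = 60, 30
    loc = rng.integers(0, 2, n).astype(float)
    X = np.zeros((n, p))
    X[:, :5] = (rng.random((n, 5)) < (0.2 + 0.6 * loc[:, None])).astype(float)
    feats = _dense_features(X)
    amap = fit_voxelwise_inverse(feats, loc, rng.normal(64, 10, n))
    assert amap.weights.reshape(-1)[:5].mean() > 0


def test_rescale_for_display():
    w = np.zeros((4, 4, 4))
    w[0, 0, 0] = 10.0
    w[1, 1, 1] = 5.0
    w[2, 2, 2] = 3.0
    amap_like = type("A", (), {})()
    from wmhmap.association import AssociationMap
    amap = AssociationMap(w, 0.0, {}, (1, 1, 1), {})
    pos, neg, flagged = rescale_for_display(amap, 0.5)
    assert pos[0, 0, 0] == 1.0        # maximum clips at 1
    assert pos[1, 1, 1] == 1.0        # exactly half of max hits the boundary
    assert pos[2, 2, 2] == pytest.approx(3.0 / 5.0)
    assert flagged                    # negative half is all-zero
    assert np.all(neg == 0)
    # suprathreshold(1.0) after rescale == voxels >= 50% of max in the raw map
    assert (pos >= 1.0).sum() == (w >= 0.5 * w.max()).sum()
    with pytest.raises(ValueError, match="fraction"):
        rescale_for_display(amap, 0.0)
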