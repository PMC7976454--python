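"""Voxel-wise KW maps, BH-FDR behaviour, suprathreshold counting, battery."""

import numpy as np
import pytest

from wmhmap import (GroupContrast, LesionMask, build_4d, contrast_groups,
                    count_significant, fdr_bh, run_contrast_battery, voxelwise_kw)
from wmhmap.voxel_stats import VoxelStatMap, default_battery


def _random_stack(rng, n=20, dims=(6, 6, 6), p=0.4):
    masks = [LesionMask((rng.random(dims) < p).astype(np.uint8), (1, 1, 1))
             for _ in range(n)]
    ids = [f"s{i}" for i in range(n)]
    return build_4d(masks, ids), ids


def _kw_binary_oracle(values, labels):
    """Scalar midrank KW with tie correction, computed from first principles."""
    values = np.asarray(values, float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    for g in np.unique(labels):
        r = ranks[np.asarray(labels) == g]
        h += len(r) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, t = np.unique(values, return_counts=True)
    tie = 1.0 - (t**3 - t).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def test_unlesioned_voxel_excluded(rng):
    stack, ids = _random_stack(rng, n=10)
    stack.stack[0, 0, 0, :] = 0
    smap = voxelwise_kw(stack, {"a": ids[:5], "b": ids[5:]}, min_overlap=1)
    assert not smap.tested_mask[0, 0, 0]
    assert np.isnan(smap.P[0, 0, 0])


def test_equal_proportions_give_null(rng):
    dims = (4, 4, 4)
    masks = []
    for i in range(20):
        v = np.zeros(dims, dtype=np.uint8)
        if (i % 10) < 3:  # 3/10 lesioned in each group at every voxel
            v[:] = 1
        masks.append(LesionMask(v, (1, 1, 1)))
    ids = [f"s{i}" for i in range(20)]
    stack = build_4d(masks, ids)
    smap = voxelwise_kw(stack, {"a": ids[:10], "b": ids[10:]}, min_overlap=1)
    assert np.allclose(smap.H[smap.tested_mask], 0.0)
    assert np.allclose(smap.P[smap.tested_mask], 1.0)


def test_voxelwise_matches_scalar_oracle(rng):
    from scipy import stats
    stack, ids = _random_stack(rng, n=20)
    groups = {"a": ids[:8], "b": ids[8:]}
    smap = voxelwise_kw(stack, groups, min_overlap=2)
    labels = np.array(["a"] * 8 + ["b"] * 12)
    data = stack.stack.reshape(-1, 20)
    tested = smap.tested_mask.reshape(-1)
    for idx in np.flatnonzero(tested)[:50]:
        values = data[idx].astype(float)
        h_oracle = _kw_binary_oracle(values, labels)
        assert smap.H.reshape(-1)[idx] == pytest.approx(h_oracle, abs=1e-10)
        p_oracle = 1.0 if h_oracle == 0 else stats.chi2.sf(h_oracle, 1)
        assert smap.P.reshape(-1)[idx] == pytest.approx(p_oracle, abs=1e-10)


def test_relabel_invariance(rng):
    stack, ids = _random_stack(rng, n=16)
    a = voxelwise_kw(stack, {"t": ids[:6], "c": ids[6:]}, 2)
    b = voxelwise_kw(stack, {"t": ids[6:], "c": ids[:6]}, 2)
    assert np.allclose(a.H[a.tested_mask], b.H[b.tested_mask], atol=1e-12)


def test_voxelwise_errors(rng):
    stack, ids = _random_stack(rng, n=6)
    with pytest.raises(ValueError, match="empty group"):
        voxelwise_kw(stack, {"a": [], "b": ids}, 1)
    with pytest.raises(ValueError, match="min_overlap"):
        voxelwise_kw(stack, {"a": ids[:3], "b": ids[3:]}, 100)


def _statmap_from_pvals(pvals, dims=(10, 10, 10)):
    p = np.full(dims, np.nan)
    tested = np.zeros(dims, dtype=bool)
    flat = p.reshape(-1)
    flat[:len(pvals)] = pvals
    tested.reshape(-1)[:len(pvals)] = True
    return VoxelStatMap(tested_mask=tested, H=np.zeros(dims), P=p,
                        voxel_dims_mm=(1.0, 1.0, 1.0))


def test_bh_hand_example():
    """Step-up on {0.001, 0.02, 0.9} at alpha=0.05 rejects the first two."""
    smap = _statmap_from_pvals([0.001, 0.02, 0.9], dims=(3, 1, 1))
    decisions, threshold = fdr_bh(smap, 0.05)
    assert decisions.reshape(-1).tolist() == [True, True, False]
    assert threshold == pytest.approx(0.02)


def test_bh_no_rejections_on_flat_pvals():
    smap = _statmap_from_pvals([0.5] * 1000)
    decisions, threshold = fdr_bh(smap, 0.05)
    assert decisions.sum() == 0 and threshold == 0.0


def test_bh_decisions_nested_in_alpha(rng):
    pvals = rng.random(500) ** 2
    smap = _statmap_from_pvals(pvals)
    d01, _ = fdr_bh(smap, 0.01)
    d05, _ = fdr_bh(smap, 0.05)
    assert (d01 <= d05).all()          # rejections monotone in alpha
    n01, _ = count_significant(smap, 0.01)
    n05, _ = count_significant(smap, 0.05)
    assert n01 <= n05


def test_bh_rejects_empty_family():
    smap = _statmap_from_pvals([])
    with pytest.raises(ValueError, match="family"):
        fdr_bh(smap, 0.05)


@pytest.mark.parametrize("n_voxels,expected_ml", [
    (148639, 148.64),
    (14253, 14.25),
    (5530, 5.53),
])
def test_count_to_ml_at_1mm(n_voxels, expected_ml):
    dims = (60, 60, 60)
    smap = _statmap_from_pvals(np.zeros(n_voxels), dims=dims)
    decisions = np.zeros(dims, dtype=bool)
    decisions.reshape(-1)[:n_voxels] = True
    smap.decisions[0.05] = decisions
    n, ml = count_significant(smap, 0.05)
    assert n == n_voxels
    assert round(ml, 2) == expected_ml


def test_count_requires_computed_cutoff():
    smap = _statmap_from_pvals([0.5])
    with pytest.raises(KeyError, match="cutoff"):
        count_significant(smap, 0.01)


def test_contrast_groups_disjoint_and_cover(small_cohort):
    t = small_cohort.table
    contrast = GroupContrast("RSSI", "centrum semiovale", risk_factor="smoker")
    target, comparison = contrast_groups(t, contrast)
    assert not set(target) & set(comparison)
    carriers = t[t["rssi_location_codes"].map(len) > 0]
    smoker = carriers["smoking"].isin(("current", "recent"))
    in_loc = carriers["rssi_location_codes"].map(
        lambda c: any(x[0] == "centrum semiovale" for x in c))
    expected = set(carriers.loc[in_loc & smoker, "subject_id"]) | \
        set(carriers.loc[~in_loc & ~smoker, "subject_id"])
    assert set(target) | set(comparison) == expected


def test_battery_schema_and_empty_group_flag(small_cohort):
    ids = list(small_cohort.wmh_baseline)
    stack = build_4d(small_cohort.masks("wmh_baseline"), ids)
    contrasts = default_battery() + [GroupContrast("RSSI", "cerebellum")]
    table, maps = run_contrast_battery(stack, small_cohort.table, contrasts)
    assert {"contrast", "n_target", "n_comparison", "m_tested",
            "n_sig_005", "ml_005", "n_sig_001", "ml_001"} <= set(table.columns)
    assert len(table) == len(contrasts)
    # no synthetic subject draws a cerebellar RSSI (Table-1 weight is zero)
    cereb = table[table["contrast"] == "RSSI / cerebellum"]
    assert bool(cereb["skipped_empty_group"].iloc[0])
    with pytest.raises(ValueError, match="empty group"):
        run_contrast_battery(stack, small_cohort.table,
                             [GroupContrast("RSSI", "cerebellum")],
                             on_empty="raise")
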