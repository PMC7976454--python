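"""Volume arithmetic, evolution-map conservation, per-location summaries."""

import numpy as np
import pandas as pd
import pytest

from wmhmap import (LesionMask, change_volume, evolution_mask, mask_volume_ml,
                    pct_icv, summarize_by_location)
from wmhmap.volumetrics import CODE_PROGRESSED, CODE_REGRESSED, CODE_STABLE


def _mask_with_n(n, dims=(32, 32, 32), vox=(1.0, 1.0, 1.0)):
    values = np.zeros(dims, dtype=np.uint8)
    values.reshape(-1)[:n] = 1
    return LesionMask(values, vox)


@pytest.mark.parametrize("n_voxels,vox,expected", [
    (14253, (1, 1, 1), 14.25),   # voxel count / ml pairing at 1 mm isotropic
    (0, (1, 1, 1), 0.0),
    (100, (2, 2, 2), 0.8),
])
def test_mask_volume_ml(n_voxels, vox, expected):
    dims = (32, 32, 32) if n_voxels < 32**3 else (64, 64, 64)
    assert round(mask_volume_ml(_mask_with_n(n_voxels, dims, vox)), 2) == expected


def test_pct_icv():
    assert pct_icv(0.0, 1469.2) == 0.0
    assert pct_icv(14.692, 1469.2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pct_icv(1.0, 0.0)


def test_evolution_identity_case():
    m = _mask_with_n(50, (8, 8, 8))
    emap = evolution_mask(m, m)
    assert set(np.unique(emap.codes)) <= {0, CODE_STABLE}
    assert emap.volume_ml(CODE_PROGRESSED) == emap.volume_ml(CODE_REGRESSED) == 0


def test_evolution_disjoint_voxels():
    base = np.zeros((4, 4, 4), dtype=np.uint8)
    fup = np.zeros((4, 4, 4), dtype=np.uint8)
    base[0, 0, 0] = 1
    fup[1, 1, 1] = 1
    emap = evolution_mask(LesionMask(base, (1, 1, 1)), LesionMask(fup, (1, 1, 1)))
    assert emap.codes[0, 0, 0] == CODE_REGRESSED
    assert emap.codes[1, 1, 1] == CODE_PROGRESSED


def test_evolution_conservation_random_pairs(rng):
    """vol(stable)+vol(progressed)=vol(followup); +regressed = baseline, exactly."""
    for _ in range(20):
        b = (rng.random((16, 16, 16)) > 0.6).astype(np.uint8)
        f = (rng.random((16, 16, 16)) > 0.6).astype(np.uint8)
        mb, mf = LesionMask(b, (2, 2, 2)), LesionMask(f, (2, 2, 2))
        emap = evolution_mask(mb, mf)
        # exact in voxel counts; the ml restatement is the same counts scaled
        assert np.isin(emap.codes, (CODE_STABLE, CODE_PROGRESSED)).sum() == f.sum()
        assert np.isin(emap.codes, (CODE_STABLE, CODE_REGRESSED)).sum() == b.sum()
        assert emap.volume_ml(CODE_STABLE) + emap.volume_ml(CODE_PROGRESSED) \
            == pytest.approx(mask_volume_ml(mf), abs=1e-9)
        assert emap.volume_ml(CODE_STABLE) + emap.volume_ml(CODE_REGRESSED) \
            == pytest.approx(mask_volume_ml(mb), abs=1e-9)
        # decode consistency
        assert np.array_equal(emap.baseline_mask().values, b)
        assert np.array_equal(emap.followup_mask().values, f)


def test_evolution_requires_congruence():
    with pytest.raises(ValueError, match="congruent"):
        evolution_mask(_mask_with_n(1, (4, 4, 4)), _mask_with_n(1, (5, 5, 5)))


def test_change_volume():
    base = {"subject_id": "s1", "icv_ml": 1469.2, "wmh_total_ml": 18.0}
    y1 = {"subject_id": "s1", "icv_ml": 1469.2, "wmh_total_ml": 27.41}
    dml, dpct = change_volume(base, y1)
    assert dml == pytest.approx(9.41)
    assert dpct == pytest.approx(100 * 9.41 / 1469.2)
    assert change_volume(y1, base)[0] == pytest.approx(-9.41)
    assert change_volume(base, base)[0] == 0.0
    with pytest.raises(ValueError, match="different subjects"):
        change_volume(base, {**y1, "subject_id": "s2"})


def test_change_equals_evolution_difference(rng):
    b = (rng.random((12, 12, 12)) > 0.5).astype(np.uint8)
    f = (rng.random((12, 12, 12)) > 0.5).astype(np.uint8)
    mb, mf = LesionMask(b, (3, 3, 3)), LesionMask(f, (3, 3, 3))
    emap = evolution_mask(mb, mf)
    assert emap.volume_ml(CODE_PROGRESSED) - emap.volume_ml(CODE_REGRESSED) \
        == pytest.approx(mask_volume_ml(mf) - mask_volume_ml(mb))


def test_summary_quantile_rule(small_cohort):
    """Group {1,2,3,4} ml: median 2.5, Q1 1.75, Q3 3.25 (linear interpolation)."""
    t = small_cohort.table.head(4).copy()
    t["wmh_total_ml_baseline"] = [1.0, 2.0, 3.0, 4.0]
    t["rssi_location_codes"] = [[("thalamus", "left")]] * 4
    t["rssi_volume_ml"] = 1.0
    summary = summarize_by_location(t, "RSSI")
    row = summary[(summary.region == "thalamus") & (summary.timepoint == "baseline")]
    assert row["total_median_ml"].iloc[0] == 2.5
    assert row["total_q1_ml"].iloc[0] == 1.75
    assert row["total_q3_ml"].iloc[0] == 3.25
    assert row["n"].iloc[0] == 4
    assert row["descriptive_only"].iloc[0]  # n=4 < default floor of 5


def test_summary_single_subject_group(small_cohort):
    t = small_cohort.table.head(1).copy()
    t["rssi_location_codes"] = [[("cerebellum", "right")]]
    t["rssi_volume_ml"] = 0.5
    v = float(t["wmh_total_ml_baseline"].iloc[0])
    summary = summarize_by_location(t, "RSSI")
    row = summary[(summary.region == "cerebellum") & (summary.timepoint == "baseline")]
    assert row["total_median_ml"].iloc[0] == row["total_q1_ml"].iloc[0] \
        == row["total_q3_ml"].iloc[0] == pytest.approx(v)


def test_summary_counts_match_generator(small_cohort):
    summary = summarize_by_location(small_cohort.table, "lacunes")
    expected = sum(len(c) for c in small_cohort.table["lacune_location_codes"])
    got = summary[summary.timepoint == "baseline"][
        ["n_features_left", "n_features_right"]].to_numpy().sum()
    assert got == expected


def test_summary_rejects_unknown_feature(small_cohort):
    with pytest.raises(ValueError, match="feature"):
        summarize_by_location(small_cohort.table, "microbleeds")
    with pytest.raises(ValueError, match="empty"):
        summarize_by_location(small_cohort.table.iloc[:0], "RSSI")
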