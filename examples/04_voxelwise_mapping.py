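"""Voxel-wise lesion mapping: where does WMH differ by RSSI location?

Subjects with a planted excess-WMH region (smokers with a capsular RSSI) are
compared against subjects with the RSSI elsewhere and no smoking history, one
Kruskal-Wallis test per sufficiently-lesioned voxel, Benjamini-Hochberg
corrected.  Suprathreshold counts are reported with their ml equivalents.
"""

import numpy as np

from wmhmap import (GeneratorConfig, GroupContrast, PlantedGroup, build_4d,
                    contrast_groups, count_significant, fdr_bh, generate_cohort,
                    voxelwise_kw)

region = np.zeros((32, 32, 32), dtype=bool)
region[8:18, 6:26, 18:28] = True          # 2,000-voxel planted effect

cfg = GeneratorConfig(
    n_subjects=120, seed=1, planted_region=region,
    planted_group=PlantedGroup("internal/external capsule/lentiform nucleus",
                               risk_factor="smoker"),
    planted_balance=True)
cohort = generate_cohort(cfg)
ids = list(cohort.wmh_baseline)
stack = build_4d(cohort.masks("wmh_baseline"), ids)

contrast = GroupContrast("RSSI", "internal/external capsule/lentiform nucleus",
                         risk_factor="smoker")
target, comparison = contrast_groups(cohort.table, contrast)
smap = voxelwise_kw(stack, {"target": target, "comparison": comparison},
                    min_overlap=2)
for alpha in (0.05, 0.01):
    fdr_bh(smap, alpha)
    n, ml = count_significant(smap, alpha)
    print(f"P < {alpha}: {n:,} voxels significant ({ml:.2f} ml at "
          f"{smap.voxel_dims_mm[0]:.0f} mm voxels)")

decisions = smap.decisions[0.05]
print(f"\nsensitivity inside the planted region: {decisions[region].mean():.1%}")
outside = smap.tested_mask & ~region
print(f"suprathreshold fraction elsewhere:      "
      f"{decisions[outside].sum() / outside.sum():.2%}")
print("(high sensitivity with a near-zero outside fraction shows the "
      "mass-univariate map localizes the planted group difference)")
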