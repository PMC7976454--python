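"""Ridge-penalized SGD association map between WMH evolution and RSSI location.

Per-subject evolution maps become a sparse subject x voxel matrix with
entries -1 (regressed) / 0 / +1 (progressed).  A support-vector regression
with ridge penalty 1/47, fit by stochastic gradient descent with age as an
unpenalized covariate, maps which voxels' WMH fate tracks the RSSI location.
Positive weights mark voxels whose progression is associated with the target
location; for display each sign half is rescaled to 50% of its maximum.
"""

import numpy as np

from wmhmap import (GeneratorConfig, PlantedGroup, build_change_features,
                    encode_response, evolution_mask, fit_sgd_ridge,
                    generate_cohort, rescale_for_display)

region = np.zeros((24, 24, 24), dtype=bool)
region[6:12, 6:14, 14:19] = True          # planted progression region

cfg = GeneratorConfig(
    n_subjects=80, grid_dims=(24, 24, 24), seed=3, followup_rate=1.0,
    planted_group=PlantedGroup("internal/external capsule/lentiform nucleus"),
    planted_balance=True, progression_region=region, progression_p=0.5)
cohort = generate_cohort(cfg)

emaps = {sid: evolution_mask(cohort.mask("wmh_baseline", sid),
                             cohort.mask("wmh_followup", sid))
         for sid in cohort.wmh_followup}
union = np.zeros(cfg.grid_dims, dtype=bool)
for e in emaps.values():
    union |= e.codes > 0
features = build_change_features(emaps, union)

sub = cohort.table.set_index("subject_id").loc[list(emaps)].reset_index()
y = encode_response(sub, mode="location_indicator",
                    region="internal/external capsule/lentiform nucleus")
amap = fit_sgd_ridge(features, y, covariates=sub.age.to_numpy()[:, None],
                     lam=1 / 47, epochs=50, seed=0)

inside = amap.weights[region]
outside = amap.weights[union & ~region]
print(f"feature matrix: {features.n_subjects} subjects x "
      f"{features.n_voxels:,} voxels "
      f"({features.values.nnz:,} non-zero change entries)")
print(f"mean weight inside planted progression region: {inside.mean():+.4f}")
print(f"mean weight elsewhere:                          {outside.mean():+.5f}")
pos, neg, _ = rescale_for_display(amap)
print(f"voxels at display ceiling (>= 50% of max positive weight): "
      f"{(pos >= 1.0).sum()}")
print("\nA clearly positive mean inside the planted region, against a near-zero")
print("background, shows the model attributes WMH progression to the target")
print("RSSI location group.")
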