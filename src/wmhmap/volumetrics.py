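"""Volume accounting: ml volumes, %ICV normalization, evolution maps, summaries.

Lesion volumes come straight from binary masks (voxel count x voxel volume).
For statistics they are normalized by head size as a percentage of
intracranial volume (%ICV).  WMH evolution between the two timepoints is a
ternary-coded voxel map: regressed (baseline only), stable (both), progressed
(follow-up only); never-lesioned voxels are coded 0.

Quantile convention: all medians/IQRs use linear interpolation between order
statistics (numpy default), declared once and used everywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .imaging import LesionMask
from .locations import REGIONS, HEMISPHERES

CODE_NEVER = 0
CODE_REGRESSED = 1   # baseline only
CODE_STABLE = 2      # both timepoints
CODE_PROGRESSED = 3  # follow-up only


@dataclasses.dataclass
class EvolutionMap:
    """Ternary-coded voxel map of WMH fate between baseline and 1 year."""

    codes: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    space_label: str = "template"

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.codes.shape

    def baseline_mask(self) -> LesionMask:
        values = np.isin(self.codes, (CODE_REGRESSED, CODE_STABLE)).astype(np.uint8)
        return LesionMask(values, self.voxel_dims_mm, self.space_label)

    def followup_mask(self) -> LesionMask:
        values = np.isin(self.codes, (CODE_STABLE, CODE_PROGRESSED)).astype(np.uint8)
        return LesionMask(values, self.voxel_dims_mm, self.space_label)

    def volume_ml(self, *codes: int) -> float:
        vox_ml = float(np.prod(self.voxel_dims_mm)) / 1000.0
        return float(np.isin(self.codes, codes).sum()) * vox_ml


def mask_volume_ml(mask: LesionMask) -> float:
    """Volume of a binary mask in ml: 1-voxel count x voxel volume (mm^3) / 1000."""
    return float(mask.values.sum()) * mask.voxel_volume_mm3 / 1000.0


def pct_icv(volume_ml: float, icv_ml: float) -> float:
    """Normalize a lesion volume by head size: 100 x ml / ICV ml."""
    if icv_ml <= 0:
        raise ValueError(f"icv_ml must be > 0, got {icv_ml}")
    if volume_ml < 0:
        raise ValueError(f"volume_ml must be >= 0, got {volume_ml}")
    return 100.0 * volume_ml / icv_ml


def evolution_mask(baseline: LesionMask, followup: LesionMask) -> EvolutionMap:
    """Combine baseline and follow-up WMH masks into an evolution map.

    Conservation identities hold exactly: vol(stable) + vol(progressed) equals
    the follow-up volume, vol(stable) + vol(regressed) the baseline volume.
    """
    if not baseline.congruent_with(followup):
        raise ValueError("baseline and follow-up masks are not grid-congruent")
    b = baseline.values.astype(bool)
    f = followup.values.astype(bool)
    codes = np.zeros(b.shape, dtype=np.uint8)
    codes[b & ~f] = CODE_REGRESSED
    codes[b & f] = CODE_STABLE
    codes[~b & f] = CODE_PROGRESSED
    return EvolutionMap(codes, baseline.voxel_dims_mm, baseline.space_label)


def change_volume(
    record_base: dict, record_y1: dict, field: str = "wmh_total_ml"
) -> tuple[float, float]:
    """Signed 1-year volume change for one subject: follow-up minus baseline.

    ``record_base`` / ``record_y1`` are per-timepoint dicts with at least
    ``subject_id``, ``icv_ml`` and the requested volume field.  Returns
    ``(change_ml, change_pct_icv)``; regression is negative.
    """
    if record_base["subject_id"] != record_y1["subject_id"]:
        raise ValueError(
            f"timepoint records belong to different subjects: "
            f"{record_base['subject_id']!r} vs {record_y1['subject_id']!r}"
        )
    delta_ml = float(record_y1[field]) - float(record_base[field])
    icv = float(record_base["icv_ml"])
    return delta_ml, pct_icv(abs(delta_ml), icv) * np.sign(delta_ml)


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return np.nan, np.nan, np.nan
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


_VOLUME_FIELDS = {
    "baseline": ("wmh_intense_ml_baseline", "wmh_less_intense_ml_baseline",
                 "wmh_total_ml_baseline"),
    "year1": ("wmh_intense_ml_year1", "wmh_less_intense_ml_year1",
              "wmh_total_ml_year1"),
}


def summarize_by_location(
    cohort: pd.DataFrame,
    feature: str = "RSSI",
    min_group_n: int = 5,
) -> pd.DataFrame:
    """Median (Q1, Q3) WMH volumes per lesion location x timepoint.

    A subject contributes to the row of every region in which they carry the
    feature.  Groups smaller than ``min_group_n`` are emitted but flagged
    ``descriptive_only``.  Feature counts per region/hemisphere are included.
    """
    if feature not in ("RSSI", "lacunes"):
        raise ValueError(f"unknown feature kind: {feature!r}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    col = "rssi_location_codes" if feature == "RSSI" else "lacune_location_codes"

    rows = []
    for region in REGIONS:
        in_region = cohort[col].map(
            lambda codes: any(c[0] == region for c in codes)
        )
        counts = {
            hemi: int(sum(
                sum(1 for c in codes if c == (region, hemi))
                for codes in cohort[col]
            ))
            for hemi in HEMISPHERES
        }
        for timepoint, fields in _VOLUME_FIELDS.items():
            sub = cohort[in_region]
            if timepoint == "year1":
                sub = sub[sub["has_followup"]]
            row = {
                "feature": feature,
                "region": region,
                "timepoint": timepoint,
                "n": int(len(sub)),
                "n_features_left": counts["left"],
                "n_features_right": counts["right"],
                "descriptive_only": len(sub) < min_group_n,
            }
            for name, field in zip(("intense", "less_intense", "total"), fields):
                med, q1, q3 = _median_iqr(sub[field].to_numpy(dtype=float)) \
                    if len(sub) else (np.nan, np.nan, np.nan)
                row[f"{name}_median_ml"] = med
                row[f"{name}_q1_ml"] = q1
                row[f"{name}_q3_ml"] = q3
            # %ICV twins of the same summaries
            for name, field in zip(("intense", "less_intense", "total"), fields):
                if len(sub):
                    pct = 100.0 * sub[field].to_numpy(dtype=float) / \
                        sub["icv_ml"].to_numpy(dtype=float)
                    med, q1, q3 = _median_iqr(pct)
                else:
                    med = q1 = q3 = np.nan
                row[f"{name}_median_pcticv"] = med
                row[f"{name}_q1_pcticv"] = q1
                row[f"{name}_q3_pcticv"] = q3
            rows.append(row)
    return pd.DataFrame(rows)
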