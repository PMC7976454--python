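"""Mass-univariate voxel-wise comparison of WMH maps with FDR correction.

At every voxel where enough subjects carry a lesion (the overlap floor), the
binary WMH indicator is compared between a target group (feature in a given
location, optionally restricted to carriers of a risk factor) and a
comparison group (feature elsewhere and, when conditioned, without the risk
factor) with the tie-corrected Kruskal-Wallis test.  On binary data this
reduces to a rank test on the two lesion proportions; the heavy tie
correction is essential and is computed in closed form, vectorized over the
whole grid.

Voxels below the overlap floor are excluded both from testing and from the
multiple-testing family; Benjamini-Hochberg correction is applied per
contrast over the tested family only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging import Mask4D

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclasses.dataclass
class GroupContrast:
    """One group-vs-rest comparison by lesion location, optionally risk-conditioned.

    ``feature`` is ``"RSSI"`` or ``"lacunes"``; the target group consists of
    subjects with that feature in ``region`` (and ``hemisphere`` when given)
    who, if ``risk_factor`` is set, carry the factor.  The comparison group
    consists of subjects with the feature elsewhere who (when conditioned) do
    not carry the factor.  ``risk_factor`` names a boolean cohort column
    (``smoker`` = current or recent smoker).
    """

    feature: str
    region: str
    hemisphere: str | None = None
    risk_factor: str | None = None

    def label(self) -> str:
        parts = [self.feature, self.region]
        if self.hemisphere:
            parts.append(self.hemisphere)
        if self.risk_factor:
            parts.append(self.risk_factor)
        return " / ".join(parts)


@dataclasses.dataclass
class VoxelStatMap:
    """Per-voxel statistic/p-value fields and FDR decisions for one contrast."""

    tested_mask: np.ndarray               # bool; voxels meeting the overlap floor
    H: np.ndarray                         # float; NaN outside tested_mask
    P: np.ndarray                         # float; NaN outside tested_mask
    voxel_dims_mm: tuple[float, float, float]
    decisions: dict = dataclasses.field(default_factory=dict)   # alpha -> bool field
    thresholds: dict = dataclasses.field(default_factory=dict)  # alpha -> realized p cut
    n_target: int = 0
    n_comparison: int = 0

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.tested_mask.shape

    @property
    def m_tested(self) -> int:
        return int(self.tested_mask.sum())


def contrast_groups(
    cohort: pd.DataFrame, contrast: GroupContrast
) -> tuple[list[str], list[str]]:
    """Resolve a contrast into (target ids, comparison ids).

    The analyzable sample is restricted to feature carriers; with a risk
    condition, carriers in the target location without the factor and
    carriers elsewhere with the factor are excluded, so target and comparison
    are disjoint and jointly cover the analyzable sample.
    """
    if contrast.feature not in ("RSSI", "lacunes"):
        raise ValueError(f"unknown feature kind: {contrast.feature!r}")
    col = ("rssi_location_codes" if contrast.feature == "RSSI"
           else "lacune_location_codes")

    def in_location(codes) -> bool:
        return any(
            c[0] == contrast.region
            and (contrast.hemisphere is None or c[1] == contrast.hemisphere)
            for c in codes
        )

    carriers = cohort[cohort[col].map(len) > 0]
    loc = carriers[col].map(in_location)
    if contrast.risk_factor is None:
        target = carriers.loc[loc, "subject_id"]
        comparison = carriers.loc[~loc, "subject_id"]
    else:
        if contrast.risk_factor == "smoker" and "smoker" not in carriers.columns:
            risk = carriers["smoking"].isin(("current", "recent"))
        elif contrast.risk_factor not in carriers.columns:
            raise KeyError(f"risk factor column missing: {contrast.risk_factor!r}")
        else:
            risk = carriers[contrast.risk_factor].astype(bool)
        target = carriers.loc[loc & risk, "subject_id"]
        comparison = carriers.loc[~loc & ~risk, "subject_id"]
    return list(target), list(comparison)


def _binary_kw_fields(
    counts: list[np.ndarray], sizes: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected Kruskal-Wallis on per-voxel binary indicators.

    ``counts[g]`` is the per-voxel lesion count in group g (size ``sizes[g]``).
    With only 0/1 values the rank structure is fully determined by the total
    number of ones ``a`` and zeros ``z``: zeros share rank (z+1)/2, ones share
    rank z+(a+1)/2, and the tie term is (z^3-z + a^3-a)/(N^3-N).
    """
    n_total = int(sum(sizes))
    a = np.zeros_like(counts[0], dtype=np.float64)
    for c in counts:
        a += c
    z = n_total - a
    r0 = (z + 1.0) / 2.0
    r1 = z + (a + 1.0) / 2.0
    grand = (n_total + 1.0) / 2.0
    h = np.zeros_like(a)
    for c, n_g in zip(counts, sizes):
        rbar = ((n_g - c) * r0 + c * r1) / n_g
        h += n_g * (rbar - grand) ** 2
    h *= 12.0 / (n_total * (n_total + 1.0))
    tie = 1.0 - ((z**3 - z) + (a**3 - a)) / (n_total**3 - n_total)
    degenerate = tie <= 0  # all-zero or all-one voxels: every value identical
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, tie))
    df = len(sizes) - 1
    p = np.where(degenerate, 1.0, stats.chi2.sf(h, df))
    return h, p


def voxelwise_kw(
    stack: Mask4D,
    groups: dict[str, list[str]],
    min_overlap: int = 2,
) -> VoxelStatMap:
    """Voxel-wise Kruskal-Wallis comparison of WMH presence between groups.

    ``groups`` maps group labels to subject-id lists (two groups for the
    standard location-vs-elsewhere contrast; more are allowed).  Voxels with
    fewer than ``min_overlap`` lesioned subjects overall are excluded from
    testing and from the multiple-testing family.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = []
    counts = []
    for label, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"empty group: {label!r}")
        sub = stack.subset(list(ids))
        counts.append(sub.stack.sum(axis=-1).astype(np.float64))
        sizes.append(sub.n_subjects)
    if min_overlap > sum(sizes):
        raise ValueError("min_overlap exceeds the analyzable sample size")

    total = np.zeros(stack.grid_dims, dtype=np.float64)
    for c in counts:
        total += c
    tested = total >= min_overlap

    h, p = _binary_kw_fields(counts, sizes)
    h_field = np.where(tested, h, np.nan)
    p_field = np.where(tested, p, np.nan)
    return VoxelStatMap(
        tested_mask=tested,
        H=h_field,
        P=p_field,
        voxel_dims_mm=stack.voxel_dims_mm,
        n_target=sizes[0],
        n_comparison=int(sum(sizes[1:])),
    )


def fdr_bh(stat_map: VoxelStatMap, alpha: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over the tested family; updates the map.

    Returns the decision field and the realized p cut-off (largest p value
    rejected; 0.0 when nothing is rejected).  Also records family size and
    rejection count on the map.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    tested = stat_map.tested_mask
    m = int(tested.sum())
    if m == 0:
        raise ValueError("empty testing family: no voxel met the overlap floor")
    pvals = stat_map.P[tested]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    decisions = np.zeros(stat_map.grid_dims, dtype=bool)
    decisions[tested] = reject
    threshold = float(pvals[reject].max()) if reject.any() else 0.0
    stat_map.decisions[alpha] = decisions
    stat_map.thresholds[alpha] = threshold
    return decisions, threshold


def count_significant(
    stat_map: VoxelStatMap, cutoff: float
) -> tuple[int, float]:
    """Suprathreshold voxel count and its ml equivalent at a computed cut-off."""
    if cutoff not in stat_map.decisions:
        raise KeyError(f"decisions at cutoff {cutoff} not computed; run fdr_bh first")
    n_voxels = int(stat_map.decisions[cutoff].sum())
    vox_ml = float(np.prod(stat_map.voxel_dims_mm)) / 1000.0
    return n_voxels, n_voxels * vox_ml


def default_battery(
    regions=("internal/external capsule/lentiform nucleus", "centrum semiovale"),
    features=("RSSI", "lacunes"),
    risk_factors=(None, "hypertension", "hyperlipidemia", "smoker"),
) -> list[GroupContrast]:
    """The location x risk-factor contrast grid of the standard report."""
    return [
        GroupContrast(feature=f, region=r, risk_factor=rf)
        for f in features for r in regions for rf in risk_factors
    ]


def run_contrast_battery(
    stack: Mask4D,
    cohort: pd.DataFrame,
    contrasts: list[GroupContrast],
    min_overlap: int = 2,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    on_empty: str = "skip",
) -> tuple[pd.DataFrame, dict]:
    """Run every contrast, correct per contrast, and tabulate counts/ml.

    Returns a results table (one row per contrast: group sizes, family size,
    suprathreshold voxel counts and ml at each cut-off) and the per-contrast
    VoxelStatMap objects.  Contrasts with an empty group are skipped with a
    flag when ``on_empty="skip"``, or raise when ``on_empty="raise"``.
    """
    rows = []
    maps = {}
    for contrast in contrasts:
        label = contrast.label()
        target, comparison = contrast_groups(cohort, contrast)
        row = {
            "contrast": label,
            "n_target": len(target),
            "n_comparison": len(comparison),
        }
        if len(target) == 0 or len(comparison) == 0:
            if on_empty == "raise":
                raise ValueError(f"empty group in contrast {label!r}")
            row.update({"m_tested": 0, "skipped_empty_group": True})
            for alpha in alphas:
                tag = str(alpha).replace("0.", "0")
                row[f"n_sig_{tag}"] = np.nan
                row[f"ml_{tag}"] = np.nan
            rows.append(row)
            continue
        stat_map = voxelwise_kw(
            stack, {"target": target, "comparison": comparison}, min_overlap
        )
        row["m_tested"] = stat_map.m_tested
        row["skipped_empty_group"] = False
        for alpha in alphas:
            fdr_bh(stat_map, alpha)
            n_vox, ml = count_significant(stat_map, alpha)
            tag = str(alpha).replace("0.", "0")
            row[f"n_sig_{tag}"] = n_vox
            row[f"ml_{tag}"] = ml
        maps[label] = stat_map
        rows.append(row)
    return pd.DataFrame(rows), maps
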