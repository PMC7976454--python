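"""Synthetic lacunar-stroke cohort generator.

Clinical MRI cohorts of lacunar stroke patients are rarely deposited, so this
module generates complete synthetic study inputs with the statistical
structure the downstream analyses assume:

* a cohort table with demographics and vascular risk factors matching the
  marginal prevalences of the reference sample (n=118, mean age 64.93 y,
  hypertension 69.5%, ...),
* per-subject binary WMH masks (baseline and, for followed-up subjects,
  1-year), an RSSI mask and an old-lesion mask on a common grid,
* planted, recoverable effects: lacune count with expectation linear in
  baseline WMH %ICV, 1-year WMH volume change with expectation linear in RSSI
  volume, and optionally an excess-WMH region for one location × risk-factor
  group (the substrate for voxel-wise mapping tests).

The WMH spatial model is a fixed smooth probability template with a
periventricular-like gradient (probability highest near the grid
center-line), scaled by a per-subject log-normal severity factor, sampled
voxel-wise by Bernoulli draws and morphologically closed so that lesions are
spatially clustered rather than salt-and-pepper.

All randomness flows from a single seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import LesionMask, write_cohort, write_mask
from .locations import HEMISPHERES, REGIONS

# Table-1 feature counts per (region, hemisphere): the default draw weights.
RSSI_LOCATION_COUNTS = {
    ("internal/external capsule/lentiform nucleus", "left"): 9,
    ("internal/external capsule/lentiform nucleus", "right"): 13,
    ("internal border zone", "left"): 0,
    ("internal border zone", "right"): 0,
    ("centrum semiovale", "left"): 16,
    ("centrum semiovale", "right"): 18,
    ("thalamus", "left"): 6,
    ("thalamus", "right"): 7,
    ("brainstem", "left"): 3,
    ("brainstem", "right"): 7,
    ("cerebellum", "left"): 0,
    ("cerebellum", "right"): 0,
    ("optical radiation", "left"): 2,
    ("optical radiation", "right"): 0,
}

LACUNE_LOCATION_COUNTS = {
    ("internal/external capsule/lentiform nucleus", "left"): 15,
    ("internal/external capsule/lentiform nucleus", "right"): 17,
    ("internal border zone", "left"): 1,
    ("internal border zone", "right"): 1,
    ("centrum semiovale", "left"): 14,
    ("centrum semiovale", "right"): 18,
    ("thalamus", "left"): 4,
    ("thalamus", "right"): 3,
    ("brainstem", "left"): 2,
    ("brainstem", "right"): 3,
    ("cerebellum", "left"): 2,
    ("cerebellum", "right"): 1,
    ("optical radiation", "left"): 5,
    ("optical radiation", "right"): 2,
}

# anatomical anchors as fractions of the grid (left-hemisphere x; right mirrors)
_REGION_ANCHORS = {
    "internal/external capsule/lentiform nucleus": (0.35, 0.50, 0.45),
    "internal border zone": (0.30, 0.50, 0.55),
    "centrum semiovale": (0.35, 0.50, 0.70),
    "thalamus": (0.42, 0.50, 0.50),
    "brainstem": (0.47, 0.45, 0.25),
    "cerebellum": (0.40, 0.30, 0.20),
    "optical radiation": (0.35, 0.30, 0.50),
}

_RISK_FACTORS = ("diabetes", "hypertension", "hyperlipidemia")


@dataclasses.dataclass
class PlantedGroup:
    """Designation of the subject group that receives excess WMH probability.

    Members are subjects whose primary RSSI falls in ``region`` (optionally a
    specific ``hemisphere``) and, if ``risk_factor`` is set, who carry that
    risk factor ("smoker" means current-or-recent smoking).
    """

    region: str
    hemisphere: str | None = None
    risk_factor: str | None = None


@dataclasses.dataclass
class GeneratorConfig:
    n_subjects: int = 118
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    voxel_dims_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    age_mean_sd: tuple[float, float] = (64.93, 11.75)
    icv_mean_sd: tuple[float, float] = (1469.20, 139.82)
    male_fraction: float = 67 / 118
    prevalence: dict = dataclasses.field(
        default_factory=lambda: {
            "diabetes": 12 / 118,
            "hypertension": 82 / 118,
            "hyperlipidemia": 73 / 118,
        }
    )
    # Table-1 counts are 46/5/31/35 of 117 smoking-status reporters
    smoking_prevalence: dict = dataclasses.field(
        default_factory=lambda: {
            "current": 46 / 117,
            "recent": 5 / 117,
            "ex": 31 / 117,
            "never": 35 / 117,
        }
    )
    rssi_positive_rate: float = 79 / 118
    multi_cluster_rate: float = 0.0       # 6/118 in the reference sample when enabled
    old_lesion_rate: float = 42 / 118
    followup_rate: float = 88 / 118
    rssi_location_weights: dict = dataclasses.field(
        default_factory=lambda: dict(RSSI_LOCATION_COUNTS)
    )
    lacune_location_weights: dict = dataclasses.field(
        default_factory=lambda: dict(LACUNE_LOCATION_COUNTS)
    )
    # planted, recoverable effects
    effect_lacune_slope: float = 0.37     # expected lacunes per unit WMH %ICV
    lacune_base_rate: float = 0.3         # floor of the Poisson rate
    effect_change_slope: float = 2.9      # expected WMH change (ml) per ml RSSI
    progression_base_ml: float = 0.5      # RSSI-independent expected progression
    regression_mean_ml: float = 0.5       # expected WMH regression volume
    # WMH spatial model
    severity_median: float = 0.10
    severity_sigma: float = 0.9
    severity_cap: float = 0.45   # truncates the log-normal's implausible tail
    template_sigma_frac: float = 0.18
    template_peak: float = 0.5
    intense_fraction: float = 0.3         # top template-quantile share coded intense
    # lesion size models (ml, log-normal medians / log-sd)
    rssi_volume_median_ml: float = 1.0
    rssi_volume_sigma: float = 0.6
    old_volume_median_ml: float = 1.2
    old_volume_sigma: float = 0.7
    # optional planted spatial effects (both keyed to planted_group membership)
    planted_region: np.ndarray | list | None = None   # boolean grid or coord list
    planted_group: PlantedGroup | None = None
    planted_p_base: float = 0.15
    planted_p_target: float = 0.60
    planted_balance: bool = False
    progression_region: np.ndarray | list | None = None  # excess 1-year progression
    progression_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if any(int(d) <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be strictly positive")
        if any(float(v) <= 0 for v in self.voxel_dims_mm):
            raise ValueError("voxel_dims_mm must be strictly positive")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.voxel_dims_mm = tuple(float(v) for v in self.voxel_dims_mm)
        for name, p in {**self.prevalence, **self.smoking_prevalence}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name!r} not in [0,1]: {p}")
        for name in ("rssi_positive_rate", "followup_rate", "old_lesion_rate",
                     "multi_cluster_rate", "planted_p_base", "planted_p_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} not in [0,1]: {v}")
        if abs(sum(self.smoking_prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("smoking-level probabilities must sum to 1")
        for weights, label in (
            (self.rssi_location_weights, "rssi_location_weights"),
            (self.lacune_location_weights, "lacune_location_weights"),
        ):
            total = sum(weights.values())
            if total <= 0 or any(w < 0 for w in weights.values()):
                raise ValueError(f"{label} not normalizable")
        if self.planted_region is not None:
            self.planted_region = _as_region_mask(self.planted_region, self.grid_dims)
            if self.planted_group is None:
                raise ValueError("planted_region requires planted_group")
        if self.progression_region is not None:
            self.progression_region = _as_region_mask(
                self.progression_region, self.grid_dims
            )
            if self.planted_group is None:
                raise ValueError("progression_region requires planted_group")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims_mm)) / 1000.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("rssi_location_weights", "lacune_location_weights"):
            d[key] = {f"{region},{hemi}": v for (region, hemi), v in d[key].items()}
        if self.planted_region is not None:
            d["planted_region"] = np.argwhere(self.planted_region).tolist()
        if self.progression_region is not None:
            d["progression_region"] = np.argwhere(self.progression_region).tolist()
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def _as_region_mask(region, grid_dims) -> np.ndarray:
    arr = np.asarray(region)
    if arr.dtype == bool and arr.shape == tuple(grid_dims):
        return arr
    coords = arr.reshape(-1, 3).astype(int)
    mask = np.zeros(grid_dims, dtype=bool)
    mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    return mask


def wmh_probability_template(
    grid_dims: tuple[int, int, int],
    sigma_frac: float = 0.18,
    peak: float = 0.5,
) -> np.ndarray:
    """Fixed spatial WMH probability template.

    Probability decays with distance from the grid's anterior-posterior
    center-line (a crude periventricular gradient); uniform along that line.
    """
    nx, ny, nz = grid_dims
    x = np.arange(nx)[:, None, None]
    z = np.arange(nz)[None, None, :]
    sigma = sigma_frac * min(nx, nz)
    d2 = (x - (nx - 1) / 2.0) ** 2 + (z - (nz - 1) / 2.0) ** 2
    template = peak * np.exp(-d2 / (2.0 * sigma**2))
    return np.broadcast_to(template, grid_dims).copy()


@dataclasses.dataclass
class SyntheticCohort:
    """In-memory synthetic study: cohort table plus per-subject mask sets."""

    table: pd.DataFrame
    wmh_baseline: dict
    wmh_intense: dict
    wmh_less_intense: dict
    wmh_followup: dict
    rssi: dict
    old_lesion: dict
    template: np.ndarray
    config: GeneratorConfig

    def mask(self, kind: str, subject_id: str) -> LesionMask:
        store = getattr(self, kind)
        return LesionMask(store[subject_id], self.config.voxel_dims_mm)

    def masks(self, kind: str, subject_ids=None) -> list[LesionMask]:
        store = getattr(self, kind)
        ids = list(store) if subject_ids is None else list(subject_ids)
        return [LesionMask(store[s], self.config.voxel_dims_mm) for s in ids]

    def write(self, outdir: str | Path) -> dict:
        """Write cohort CSV, all masks as NIfTI, and generator provenance."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(self.table, outdir / "cohort.csv")
        self.config.to_json(outdir / "generator_config.json")
        written: dict = {"cohort": outdir / "cohort.csv"}
        for kind in ("wmh_baseline", "wmh_intense", "wmh_less_intense",
                     "wmh_followup", "rssi", "old_lesion"):
            store = getattr(self, kind)
            paths = []
            for sid, values in store.items():
                p = outdir / "masks" / kind / f"{sid}.nii.gz"
                write_mask(LesionMask(values, self.config.voxel_dims_mm), p)
                paths.append(p)
            written[kind] = paths
        return written


def _draw_location(rng, weights: dict, exclude=None):
    items = [(code, w) for code, w in weights.items()
             if w > 0 and (exclude is None or code[0] != exclude)]
    if not items:
        items = [(code, w) for code, w in weights.items() if w > 0]
    codes, w = zip(*items)
    p = np.asarray(w, dtype=float)
    p /= p.sum()
    return codes[rng.choice(len(codes), p=p)]


def _sphere_mask(grid_dims, center, n_voxels) -> np.ndarray:
    """Quasi-spherical blob of ~n_voxels around center (clipped at bounds)."""
    mask = np.zeros(grid_dims, dtype=np.uint8)
    if n_voxels <= 0:
        return mask
    radius = max(1.0, (3.0 * n_voxels / (4.0 * np.pi)) ** (1.0 / 3.0))
    lo = [max(0, int(np.floor(c - radius - 1))) for c in center]
    hi = [min(d, int(np.ceil(c + radius + 2))) for c, d in zip(center, grid_dims)]
    xs, ys, zs = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip((xs, ys, zs), center))
    sub = (d2 <= radius**2).astype(np.uint8)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _anchor_voxel(region: str, hemi: str, grid_dims, rng) -> tuple[int, ...]:
    fx, fy, fz = _REGION_ANCHORS[region]
    if hemi == "right":
        fx = 1.0 - fx
    center = np.array([fx, fy, fz]) * (np.asarray(grid_dims) - 1)
    jitter = rng.integers(-2, 3, size=3)
    return tuple(int(np.clip(c + j, 1, d - 2))
                 for c, j, d in zip(center, jitter, grid_dims))


_STRUCT = ndimage.generate_binary_structure(3, 3)  # 26-connectivity


def _sample_adjacent(rng, base: np.ndarray, template: np.ndarray, count: int,
                     max_rings: int = 6) -> np.ndarray:
    """Pick ``count`` progression voxels from successive dilation rings of ``base``.

    If the rings run out (tiny baseline lesions), the remainder is drawn from
    the highest-template voxels outside the mask so that the planted expected
    progression volume is met without bias.
    """
    chosen = np.zeros(base.shape, dtype=bool)
    current = base.astype(bool)
    remaining = count
    for _ in range(max_rings):
        if remaining <= 0:
            break
        dilated = ndimage.binary_dilation(current, structure=_STRUCT)
        ring = np.argwhere(dilated & ~current & ~chosen)
        if len(ring) == 0:
            current = dilated
            continue
        take = min(remaining, len(ring))
        idx = rng.choice(len(ring), size=take, replace=False)
        chosen[tuple(ring[idx].T)] = True
        remaining -= take
        current = dilated
    if remaining > 0:
        free = ~(base.astype(bool) | chosen)
        cand = np.argwhere(free)
        if len(cand):
            order = np.argsort(-template[free])
            take = min(remaining, len(cand))
            sel = cand[order[:take]]
            chosen[tuple(sel.T)] = True
    return chosen


def _empty_table() -> pd.DataFrame:
    cols = [
        "subject_id", "age", "sex", "diabetes", "hypertension", "hyperlipidemia",
        "smoking", "rssi_location_codes", "rssi_volume_ml", "lacune_count",
        "lacune_location_codes", "old_lesion_volume_ml", "icv_ml", "has_followup",
        "wmh_total_ml_baseline", "wmh_intense_ml_baseline",
        "wmh_less_intense_ml_baseline", "wmh_total_ml_year1",
        "wmh_intense_ml_year1", "wmh_less_intense_ml_year1",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full synthetic study: cohort table and all mask sets.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    grid = config.grid_dims
    vox_ml = config.voxel_volume_ml
    template = wmh_probability_template(
        grid, config.template_sigma_frac, config.template_peak
    )
    planted = config.planted_region

    rows = []
    stores = {k: {} for k in ("wmh_baseline", "wmh_intense", "wmh_less_intense",
                              "wmh_followup", "rssi", "old_lesion")}

    for i in range(n):
        sid = f"S{i:04d}"
        age = float(rng.normal(*config.age_mean_sd))
        sex = "M" if rng.random() < config.male_fraction else "F"
        risks = {rf: bool(rng.random() < config.prevalence[rf])
                 for rf in _RISK_FACTORS}
        levels = list(config.smoking_prevalence)
        probs = np.array([config.smoking_prevalence[l] for l in levels])
        smoking = levels[rng.choice(len(levels), p=probs / probs.sum())]
        icv = float(max(800.0, rng.normal(*config.icv_mean_sd)))
        has_followup = bool(rng.random() < config.followup_rate)

        # --- RSSI presence and location -----------------------------------
        is_target = False
        pg = config.planted_group
        if pg is not None and config.planted_balance:
            # deterministic half/half split into the target group and the
            # "feature elsewhere, no risk factor" comparison group
            is_target = i < n // 2
            has_rssi = True
            if is_target:
                hemi = pg.hemisphere or HEMISPHERES[int(rng.random() < 0.5)]
                locations = [(pg.region, hemi)]
                if pg.risk_factor == "smoker":
                    smoking = "current"
                elif pg.risk_factor is not None:
                    risks[pg.risk_factor] = True
            else:
                locations = [_draw_location(rng, config.rssi_location_weights,
                                            exclude=pg.region)]
                if pg.risk_factor == "smoker":
                    smoking = "never"
                elif pg.risk_factor is not None:
                    risks[pg.risk_factor] = False
        else:
            has_rssi = rng.random() < config.rssi_positive_rate
            locations = []
            if has_rssi:
                locations = [_draw_location(rng, config.rssi_location_weights)]
                if rng.random() < config.multi_cluster_rate:
                    second = _draw_location(rng, config.rssi_location_weights,
                                            exclude=locations[0][0])
                    locations.append(second)
            if pg is not None and has_rssi:
                loc_ok = locations[0][0] == pg.region and (
                    pg.hemisphere is None or locations[0][1] == pg.hemisphere
                )
                if pg.risk_factor == "smoker":
                    risk_ok = smoking in ("current", "recent")
                elif pg.risk_factor is not None:
                    risk_ok = risks[pg.risk_factor]
                else:
                    risk_ok = True
                is_target = loc_ok and risk_ok

        # --- RSSI mask ------------------------------------------------------
        rssi_mask = np.zeros(grid, dtype=np.uint8)
        if has_rssi and locations:
            target_ml = float(np.exp(
                rng.normal(np.log(config.rssi_volume_median_ml),
                           config.rssi_volume_sigma)
            ))
            cluster_ml = [target_ml] + [target_ml * 0.5] * (len(locations) - 1)
            sizes = []
            for code, ml in zip(locations, cluster_ml):
                center = _anchor_voxel(code[0], code[1], grid, rng)
                blob = _sphere_mask(grid, center, int(round(ml / vox_ml)))
                sizes.append(int(blob.sum()))
                rssi_mask |= blob
            # keep cluster order = decreasing realized size (primary first)
            order = np.argsort(-np.asarray(sizes), kind="stable")
            locations = [locations[j] for j in order]
        rssi_ml = float(rssi_mask.sum()) * vox_ml
        if rssi_ml == 0:
            locations = []

        # --- baseline WMH ----------------------------------------------------
        severity = float(np.exp(rng.normal(np.log(config.severity_median),
                                           config.severity_sigma)))
        severity = min(severity, config.severity_cap)
        prob = np.clip(severity * template, 0.0, 0.98)
        if planted is not None:
            prob[planted] = config.planted_p_target if is_target else config.planted_p_base
        wmh = (rng.random(grid) < prob)
        wmh = ndimage.binary_closing(wmh, structure=_STRUCT)
        wmh = wmh.astype(np.uint8)

        # intense tier: lesion voxels whose template value is in the top
        # ``intense_fraction`` of template values over the lesion
        intense = np.zeros(grid, dtype=np.uint8)
        lesion_idx = wmh.astype(bool)
        if lesion_idx.any():
            tvals = template[lesion_idx]
            cut = np.quantile(tvals, 1.0 - config.intense_fraction)
            intense[lesion_idx & (template >= cut)] = 1
        less = (wmh & ~intense.astype(bool)).astype(np.uint8)

        wmh_ml = float(wmh.sum()) * vox_ml
        wmh_pct = 100.0 * wmh_ml / icv

        # --- lacunes: Poisson with rate linear in WMH %ICV -------------------
        lam = config.lacune_base_rate + config.effect_lacune_slope * wmh_pct
        lacune_count = int(rng.poisson(max(lam, 0.0)))
        lacune_locations = [
            _draw_location(rng, config.lacune_location_weights)
            for _ in range(lacune_count)
        ]

        # --- old stroke lesion ----------------------------------------------
        old_mask = np.zeros(grid, dtype=np.uint8)
        if rng.random() < config.old_lesion_rate:
            code = _draw_location(rng, config.lacune_location_weights)
            center = _anchor_voxel(code[0], code[1], grid, rng)
            ml = float(np.exp(rng.normal(np.log(config.old_volume_median_ml),
                                         config.old_volume_sigma)))
            old_mask = _sphere_mask(grid, center, int(round(ml / vox_ml)))
        old_ml = float(old_mask.sum()) * vox_ml

        # --- 1-year follow-up: confluent progression + boundary regression ---
        followup = None
        fu_ml = fu_int_ml = fu_less_ml = np.nan
        if has_followup:
            target_prog_ml = (config.progression_base_ml
                              + config.effect_change_slope * rssi_ml)
            prog_count = int(rng.poisson(max(target_prog_ml, 0.0) / vox_ml))
            prog = _sample_adjacent(rng, wmh, template, prog_count)
            regr_count = int(rng.poisson(config.regression_mean_ml / vox_ml))
            interior_boundary = wmh.astype(bool) & ~ndimage.binary_erosion(
                wmh.astype(bool), structure=_STRUCT
            )
            bnd = np.argwhere(interior_boundary)
            regr = np.zeros(grid, dtype=bool)
            if len(bnd) and regr_count > 0:
                take = min(regr_count, len(bnd))
                idx = rng.choice(len(bnd), size=take, replace=False)
                regr[tuple(bnd[idx].T)] = True
            followup = ((wmh.astype(bool) | prog) & ~regr).astype(np.uint8)
            if config.progression_region is not None and is_target:
                extra = (rng.random(grid) < config.progression_p) \
                    & config.progression_region
                followup = (followup.astype(bool) | extra).astype(np.uint8)
            fu_idx = followup.astype(bool)
            fu_int = np.zeros(grid, dtype=np.uint8)
            if fu_idx.any():
                tvals = template[fu_idx]
                cut = np.quantile(tvals, 1.0 - config.intense_fraction)
                fu_int[fu_idx & (template >= cut)] = 1
            fu_ml = float(followup.sum()) * vox_ml
            fu_int_ml = float(fu_int.sum()) * vox_ml
            fu_less_ml = fu_ml - fu_int_ml

        stores["wmh_baseline"][sid] = wmh
        stores["wmh_intense"][sid] = intense
        stores["wmh_less_intense"][sid] = less
        stores["rssi"][sid] = rssi_mask
        stores["old_lesion"][sid] = old_mask
        if followup is not None:
            stores["wmh_followup"][sid] = followup

        rows.append({
            "subject_id": sid,
            "age": age,
            "sex": sex,
            **risks,
            "smoking": smoking,
            "rssi_location_codes": locations,
            "rssi_volume_ml": rssi_ml,
            "lacune_count": lacune_count,
            "lacune_location_codes": lacune_locations,
            "old_lesion_volume_ml": old_ml,
            "icv_ml": icv,
            "has_followup": has_followup,
            "wmh_total_ml_baseline": wmh_ml,
            "wmh_intense_ml_baseline": float(intense.sum()) * vox_ml,
            "wmh_less_intense_ml_baseline": float(less.sum()) * vox_ml,
            "wmh_total_ml_year1": fu_ml,
            "wmh_intense_ml_year1": fu_int_ml,
            "wmh_less_intense_ml_year1": fu_less_ml,
        })

    table = pd.DataFrame(rows) if rows else _empty_table()
    return SyntheticCohort(table=table, template=template, config=config,
                           **stores)


def generate_structural_pair(
    wmh_mask: np.ndarray,
    intense_mask: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    background: float = 0.2,
    less_level: float = 0.6,
    intense_level: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """FLAIR-like / T2-like intensity volumes for a planted WMH mask.

    WMH voxels are brighter than background in both channels, and the intense
    subset brighter than the less-intense subset; independent additive
    Gaussian noise of the given SD is applied to each channel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    wmh = np.asarray(wmh_mask).astype(bool)
    intense = np.asarray(intense_mask).astype(bool)
    base = np.full(wmh.shape, background, dtype=np.float64)
    base[wmh] = less_level
    base[intense] = intense_level
    rng = np.random.default_rng(seed)
    a = base + (rng.normal(0.0, noise_sd, wmh.shape) if noise_sd > 0 else 0.0)
    b = base + (rng.normal(0.0, noise_sd, wmh.shape) if noise_sd > 0 else 0.0)
    return a, b
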