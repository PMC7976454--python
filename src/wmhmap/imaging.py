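"""NIfTI lesion-mask and cohort-table I/O, grid congruence, and 4D stacking.

All voxel-wise analyses in this package operate on *congruent* binary masks:
same grid dimensions, same voxel size, same declared space label.  Inputs are
assumed already co-registered to a common template; anything else is rejected
on load rather than silently resampled.

Volumes are reoriented to the nibabel canonical (RAS) axis order on load.
Affines beyond axis permutations/flips (shears, rotations) are refused.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .locations import format_codes, parse_codes

#: |value| above this is treated as lesion when binarizing float masks.
BINARIZE_TOL = 0.5

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "smoking",
    "rssi_location_codes",
    "rssi_volume_ml",
    "lacune_count",
    "lacune_location_codes",
    "old_lesion_volume_ml",
    "icv_ml",
    "has_followup",
)

_LIST_COLUMNS = ("rssi_location_codes", "lacune_location_codes")
_BOOL_COLUMNS = ("diabetes", "hypertension", "hyperlipidemia", "has_followup")

SMOKING_LEVELS = ("current", "recent", "ex", "never")


@dataclasses.dataclass
class LesionMask:
    """A single subject's binary lesion map on a common 3D grid."""

    values: np.ndarray                      # 3D uint8 field of {0, 1}
    voxel_dims_mm: tuple[float, float, float]
    space_label: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be binary {0,1} after load")
        self.values = self.values.astype(np.uint8)
        self.voxel_dims_mm = tuple(float(v) for v in self.voxel_dims_mm)
        if len(self.voxel_dims_mm) != 3 or any(v <= 0 for v in self.voxel_dims_mm):
            raise ValueError("voxel_dims_mm must be 3 strictly positive reals")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))

    def congruent_with(self, other: "LesionMask") -> bool:
        return (
            self.grid_dims == other.grid_dims
            and np.allclose(self.voxel_dims_mm, other.voxel_dims_mm)
            and self.space_label == other.space_label
        )


@dataclasses.dataclass
class Mask4D:
    """Subject-aligned stack of congruent masks: the unit of voxel-wise statistics.

    ``stack`` has shape ``grid_dims + (n_subjects,)``; the subject axis order
    follows ``subject_ids``.
    """

    subject_ids: list[str]
    stack: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    space_label: str = "template"

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.stack.ndim != 4:
            raise ValueError("stack must be 4D (3 spatial axes + subject axis)")
        if self.stack.shape[-1] != len(self.subject_ids):
            raise ValueError("subject axis length must equal number of subject_ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in Mask4D")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.stack.shape[:3]

    @property
    def n_subjects(self) -> int:
        return self.stack.shape[-1]

    def frequency_map(self) -> np.ndarray:
        """Per-voxel lesion count across subjects."""
        return self.stack.sum(axis=-1)

    def subset(self, ids: list[str]) -> "Mask4D":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in stack: {missing}")
        sel = [index[s] for s in ids]
        return Mask4D(list(ids), self.stack[..., sel], self.voxel_dims_mm, self.space_label)


def _check_canonical_affine(affine: np.ndarray) -> None:
    # after as_closest_canonical the linear part must be diagonal (up to tiny
    # numerical noise); anything else means a rotated/sheared grid, which this
    # pipeline does not resample
    lin = np.asarray(affine)[:3, :3]
    off = lin - np.diag(np.diag(lin))
    if np.abs(off).max() > 1e-4 * max(1.0, np.abs(np.diag(lin)).max()):
        raise ValueError(
            "input affine has rotation/shear; inputs must be co-registered, "
            "axis-aligned volumes"
        )


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3D NIfTI volume in canonical axis order; return (data, voxel dims)."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    _check_canonical_affine(img.affine)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    if np.isnan(data).all():
        raise ValueError(f"{path}: volume is all-NaN")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_mask(path: str | Path, space_label: str = "template") -> LesionMask:
    """Read a NIfTI file as a binary lesion mask.

    Float values are binarized with the declared tolerance: ``|v| > 0.5 -> 1``.
    """
    data, zooms = read_volume(path)
    data = np.nan_to_num(data, nan=0.0)
    binary = (np.abs(data) > BINARIZE_TOL).astype(np.uint8)
    return LesionMask(binary, zooms, space_label)


def write_volume(
    data: np.ndarray,
    voxel_dims_mm: tuple[float, float, float],
    path: str | Path,
    dtype=np.float32,
) -> None:
    affine = np.diag(list(voxel_dims_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(voxel_dims_mm)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def write_mask(mask: LesionMask, path: str | Path) -> None:
    write_volume(mask.values, mask.voxel_dims_mm, path, dtype=np.uint8)


def build_4d(masks: list[LesionMask], ids: list[str]) -> Mask4D:
    """Concatenate congruent lesion masks into a 4D array, ordered by ``ids``."""
    if len(masks) == 0:
        raise ValueError("build_4d requires at least one mask")
    if len(masks) != len(ids):
        raise ValueError(f"{len(masks)} masks but {len(ids)} ids")
    ref = masks[0]
    for m, sid in zip(masks, ids):
        if not ref.congruent_with(m):
            raise ValueError(
                f"mask for subject {sid!r} is not grid-congruent with the first "
                f"mask (dims {m.grid_dims} vs {ref.grid_dims}, voxels "
                f"{m.voxel_dims_mm} vs {ref.voxel_dims_mm})"
            )
    stack = np.stack([m.values for m in masks], axis=-1)
    return Mask4D(list(ids), stack, ref.voxel_dims_mm, ref.space_label)


# ---------------------------------------------------------------------------
# cohort table I/O


def validate_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    bad_icv = df.loc[df["icv_ml"] <= 0, "subject_id"].tolist()
    if bad_icv:
        raise ValueError(f"non-positive icv_ml for subjects: {bad_icv}")
    bad_smoke = df.loc[~df["smoking"].isin(SMOKING_LEVELS), "subject_id"].tolist()
    if bad_smoke:
        raise ValueError(f"unknown smoking level for subjects: {bad_smoke}")
    for col in _LIST_COLUMNS:
        for sid, codes in zip(df["subject_id"], df[col]):
            if not isinstance(codes, list):
                raise ValueError(f"{col} for subject {sid!r} is not a parsed code list")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; location-code columns are parsed to lists of tuples."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    for col in _LIST_COLUMNS:
        df[col] = [parse_codes(x if isinstance(x, str) else "") for x in df[col]]
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["lacune_count"] = df["lacune_count"].astype(int)
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table to CSV (inverse of :func:`read_cohort`)."""
    validate_cohort(df)
    out = df.copy()
    for col in _LIST_COLUMNS:
        out[col] = [format_codes(codes) for codes in out[col]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def write_statmap(statmap, prefix: str | Path) -> list[Path]:
    """Write a voxel statistic map's fields as NIfTI files sharing a prefix.

    Emits ``<prefix>_H.nii.gz``, ``<prefix>_P.nii.gz``, ``<prefix>_tested.nii.gz``
    and one decision map per computed FDR cut-off.  Values outside the tested
    family are written as 0 (tested mask disambiguates).
    """
    prefix = Path(prefix)
    written = []
    vox = statmap.voxel_dims_mm
    for name, field, dtype in (
        ("H", statmap.H, np.float32),
        ("P", statmap.P, np.float32),
        ("tested", statmap.tested_mask.astype(np.uint8), np.uint8),
    ):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        write_volume(np.nan_to_num(field, nan=0.0), vox, p, dtype=dtype)
        written.append(p)
    for alpha, decisions in sorted(statmap.decisions.items()):
        tag = f"sig_{str(alpha).replace('.', 'p')}"
        p = prefix.parent / f"{prefix.name}_{tag}.nii.gz"
        write_volume(decisions.astype(np.uint8), vox, p, dtype=np.uint8)
        written.append(p)
    return written
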