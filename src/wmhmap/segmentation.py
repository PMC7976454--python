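"""WMH and stroke-lesion segmentation primitives.

WMH segmentation here is a simplified re-implementation of red-green
color-fusion thresholding: two co-registered structural volumes (e.g. FLAIR
and T2) are robustly rescaled to [0,1] and mapped to the red and green
channels; a voxel reads as WMH only when bright in *both* channels, so the
fused scalar is the channel-wise minimum.  Two thresholds on the fused scalar
split the result into intense and less-intense tiers.  This is a deliberate
simplification of the multispectral fusion tools used in practice, not a
faithful port of any of them.

Stroke lesions are delineated by seeded region growing: the 26-connected
component of the suprathreshold set containing the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .imaging import LesionMask


@dataclasses.dataclass
class FusionImage:
    """Red-green fusion of two robustly normalized structural channels."""

    red: np.ndarray
    green: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    space_label: str = "template"

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.red.shape

    @property
    def fused(self) -> np.ndarray:
        """Conjunctive fusion scalar: bright only where both channels are bright."""
        return np.minimum(self.red, self.green)


@dataclasses.dataclass
class TieredWmhMask:
    """WMH mask split into intense and less-intense signal tiers.

    Invariant: ``intense`` and ``less_intense`` are disjoint and their union
    is ``total``.
    """

    intense: LesionMask
    less_intense: LesionMask
    total: LesionMask


def _robust_rescale(volume: np.ndarray) -> np.ndarray:
    v = np.asarray(volume, dtype=np.float64)
    lo, hi = np.percentile(v, [1.0, 99.0])
    if hi <= lo:
        raise ValueError("constant (zero-range) input cannot be rescaled")
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def rg_fuse(
    seq_a: np.ndarray,
    seq_b: np.ndarray,
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    space_label: str = "template",
) -> FusionImage:
    """Map two congruent structural volumes into the red-green color space.

    Each channel is rescaled to [0,1] over its 1st-99th percentile window so
    thresholds transfer across subjects.
    """
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return FusionImage(_robust_rescale(a), _robust_rescale(b),
                       tuple(voxel_dims_mm), space_label)


def segment_wmh(fusion: FusionImage, low_thr: float, high_thr: float) -> TieredWmhMask:
    """Threshold the fusion scalar into total / intense / less-intense WMH.

    ``total`` is the set with fused signal >= low_thr; ``intense`` the subset
    >= high_thr; ``less_intense`` the difference.
    """
    if not (0.0 <= low_thr < high_thr <= 1.0):
        raise ValueError(f"need 0 <= low_thr < high_thr <= 1, got "
                         f"({low_thr}, {high_thr})")
    s = fusion.fused
    total = (s >= low_thr).astype(np.uint8)
    intense = (s >= high_thr).astype(np.uint8)
    less = (total & ~intense.astype(bool)).astype(np.uint8)
    vox = fusion.voxel_dims_mm
    return TieredWmhMask(
        intense=LesionMask(intense, vox, fusion.space_label),
        less_intense=LesionMask(less, vox, fusion.space_label),
        total=LesionMask(total, vox, fusion.space_label),
    )


_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def region_grow(
    image: np.ndarray,
    seed_voxel: tuple[int, int, int],
    intensity_floor: float,
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[LesionMask, bool]:
    """Seeded region growing for stroke-lesion delineation.

    Returns the 26-connected component of ``{image >= intensity_floor}`` that
    contains the seed, plus a flag that is True when the seed itself is below
    the floor (the returned mask is then empty — flagged, not an error).
    """
    img = np.asarray(image, dtype=np.float64)
    seed = tuple(int(c) for c in seed_voxel)
    if len(seed) != 3 or any(c < 0 or c >= d for c, d in zip(seed, img.shape)):
        raise ValueError(f"seed {seed} out of bounds for grid {img.shape}")
    if not np.isfinite(img[seed]):
        raise ValueError("image is not finite at the seed voxel")
    supra = img >= intensity_floor
    if not supra[seed]:
        empty = np.zeros(img.shape, dtype=np.uint8)
        return LesionMask(empty, voxel_dims_mm), True
    labels, _ = ndimage.label(supra, structure=_STRUCT26)
    component = (labels == labels[seed]).astype(np.uint8)
    return LesionMask(component, voxel_dims_mm), False
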