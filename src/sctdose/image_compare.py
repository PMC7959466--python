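"""HU-class construction, CT vs pseudo-CT RMSE, and DRR comparison.

The bone class collects voxels strictly above 150 HU and the soft-tissue
class voxels in [−150, 150] HU, both decided on the reference (initial) CT
only so that the two RMSE operands share one region of interest. DRRs are
orthographic parallel ray-sums of an attenuation-like value
``max(HU − hu_floor, 0)`` times the step length; the bone-only variant uses
``hu_floor = 150`` so the comparison is driven by the skull, the structure
that matters for alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ImageVolume, StructureMask, require_co_registered

__all__ = [
    "BONE_HU_THRESHOLD",
    "SOFT_TISSUE_HU_RANGE",
    "HuClassMasks",
    "Drr",
    "classify_hu",
    "rmse",
    "make_drr",
    "drr_rmse",
]

BONE_HU_THRESHOLD = 150.0  # bone: HU strictly above this
SOFT_TISSUE_HU_RANGE = (-150.0, 150.0)  # soft tissue: inclusive interval

_AXIS_ALIASES = {
    "z": 0, "axial": 0, "si": 0,
    "y": 1, "ap": 1, "anterior-posterior": 1,
    "x": 2, "lateral": 2, "lr": 2,
}


@dataclass
class HuClassMasks:
    """Bone (> 150 HU) and soft-tissue ([−150, 150] HU) masks; disjoint by
    construction (150 HU itself belongs to soft tissue only)."""

    bone: np.ndarray
    soft_tissue: np.ndarray


@dataclass
class Drr:
    """A digitally reconstructed radiograph: per-pixel path-integrated
    attenuation in HU·mm, from an orthographic parallel projection."""

    image: np.ndarray
    pixel_spacing: tuple[float, float]
    projection_axis: str


def classify_hu(reference_ct: ImageVolume) -> HuClassMasks:
    """Bone/soft-tissue class masks from the reference CT."""
    if not reference_ct.is_ct_like():
        raise ValueError(
            f"classify_hu: expected a CT-like volume, got modality {reference_ct.modality}"
        )
    hu = reference_ct.data
    bone = hu > BONE_HU_THRESHOLD
    lo, hi = SOFT_TISSUE_HU_RANGE
    soft = (hu >= lo) & (hu <= hi)
    return HuClassMasks(bone=bone, soft_tissue=soft)


def rmse(pred: ImageVolume, true: ImageVolume, mask) -> float:
    """Root mean square HU error between two co-registered volumes over a mask.

    ``mask`` may be a boolean array or a StructureMask. Symmetric in its
    image arguments; zero iff the images agree on the mask.
    """
    require_co_registered(pred, true, "rmse")
    name = "mask"
    if isinstance(mask, StructureMask):
        name = mask.name
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pred.shape:
        raise ValueError("rmse: mask shape does not match the volumes")
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"rmse: mask '{name}' is empty")
    diff = pred.data[mask] - true.data[mask]
    return float(np.sqrt(np.mean(diff**2)))


def make_drr(
    ct: ImageVolume, projection_axis: str = "ap", hu_floor: float = -1000.0
) -> Drr:
    """Orthographic DRR: per ray, integrate max(HU − hu_floor, 0) × step.

    Default projection is anterior–posterior (along y); ``hu_floor = 150``
    gives the bone-only variant.
    """
    axis_key = str(projection_axis).lower()
    if axis_key not in _AXIS_ALIASES:
        raise ValueError(
            f"make_drr: unknown projection axis {projection_axis!r}; "
            f"use one of {sorted(_AXIS_ALIASES)}"
        )
    axis = _AXIS_ALIASES[axis_key]
    atten = np.clip(ct.data - hu_floor, 0.0, None)
    image = atten.sum(axis=axis) * ct.spacing[axis]
    remaining = [d for d in range(3) if d != axis]
    return Drr(
        image=image,
        pixel_spacing=(ct.spacing[remaining[0]], ct.spacing[remaining[1]]),
        projection_axis=axis_key,
    )


def drr_rmse(ct_a: ImageVolume, ct_b: ImageVolume, projection_axis: str = "ap") -> float:
    """RMSE between bone-only DRRs of two co-registered CTs (HU·mm).

    Only pixels where either DRR carries bone signal enter the average;
    rays with no bone anywhere are excluded from N.
    """
    require_co_registered(ct_a, ct_b, "drr_rmse")
    drr_a = make_drr(ct_a, projection_axis, hu_floor=BONE_HU_THRESHOLD)
    drr_b = make_drr(ct_b, projection_axis, hu_floor=BONE_HU_THRESHOLD)
    support = (drr_a.image > 0) | (drr_b.image > 0)
    if not support.any():
        raise ValueError("drr_rmse: no bone signal in either volume")
    diff = drr_a.image[support] - drr_b.image[support]
    return float(np.sqrt(np.mean(diff**2)))
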