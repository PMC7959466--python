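"""Geometry-aware volume types, resampling and NIfTI I/O.

Conventions used throughout the package:

* voxel indices are 0-based, array axis order is ``(z, y, x)`` with ``z`` the
  slice (axial) axis;
* the world position of the *center* of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` per axis, all in millimetres;
* two grids are *co-registered* iff shape, spacing and origin match exactly.
  Every cross-volume operation either demands co-registration or resamples
  explicitly first.

Only axis-aligned geometries are supported; oblique direction cosines are
rejected at load time rather than silently reinterpreted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "StructureRole",
    "ImageVolume",
    "DoseGrid",
    "StructureMask",
    "co_registered",
    "resample_linear",
    "resample_mask",
    "dilate_isotropic",
    "read_nifti",
    "write_nifti",
]


class Modality(str, enum.Enum):
    CT = "CT"
    MRI = "MRI"
    PSEUDO_CT = "PSEUDO_CT"


#: modalities whose voxel values are Hounsfield units
CT_LIKE = frozenset({Modality.CT, Modality.PSEUDO_CT})


class StructureRole(str, enum.Enum):
    PTV = "PTV"
    GTV = "GTV"
    OAR = "OAR"
    BODY = "BODY"


def _validate_geometry(data: np.ndarray, spacing, origin, name: str) -> tuple:
    if data.ndim != 3:
        raise ValueError(f"{name}: expected a 3D lattice, got ndim={data.ndim}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError(f"{name}: spacing and origin must have 3 components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{name}: spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular axis-aligned grid.

    ``data`` holds HU for CT-like modalities and arbitrary units for MRI.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing, self.origin = _validate_geometry(
            self.data, self.spacing, self.origin, "ImageVolume"
        )
        self.modality = Modality(self.modality)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume: data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def is_ct_like(self) -> bool:
        return self.modality in CT_LIKE

    def world_coordinates(self, index: np.ndarray) -> np.ndarray:
        """World position (mm) of (possibly fractional) voxel indices."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        return ImageVolume(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            modality=self.modality if modality is None else modality,
        )


@dataclass
class DoseGrid:
    """A 3D absorbed-dose lattice in Gy sharing the volume geometry model."""

    dose: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        self.spacing, self.origin = _validate_geometry(
            self.dose, self.spacing, self.origin, "DoseGrid"
        )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("DoseGrid: dose must be finite everywhere")
        if np.any(self.dose < 0):
            raise ValueError("DoseGrid: dose must be nonnegative everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def with_dose(self, dose: np.ndarray, label: str | None = None) -> "DoseGrid":
        return DoseGrid(
            dose=dose,
            spacing=self.spacing,
            origin=self.origin,
            label=self.label if label is None else label,
        )


@dataclass
class StructureMask:
    """A named boolean volume (PTV/GTV/OAR/body) aligned to a reference grid."""

    name: str
    role: StructureRole
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing, self.origin = _validate_geometry(
            self.mask, self.spacing, self.origin, "StructureMask"
        )
        self.role = StructureRole(self.role)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_cm3

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)


def co_registered(a, b) -> bool:
    """True iff the two grids share shape, spacing and origin exactly."""
    return a.shape == b.shape and a.spacing == b.spacing and a.origin == b.origin


def require_co_registered(a, b, what: str = "operation") -> None:
    if not co_registered(a, b):
        raise ValueError(
            f"{what} requires co-registered grids: "
            f"{a.geometry()} vs {b.geometry()}; resample first"
        )


def _default_fill(volume: ImageVolume) -> float:
    # -1000 HU (air) is the physically neutral fill for CT-like volumes
    return -1000.0 if volume.is_ct_like() else 0.0


def resample_linear(
    moving: ImageVolume,
    target_geometry,
    fill_value: float | None = None,
) -> ImageVolume:
    """Trilinearly resample ``moving`` onto the geometry of ``target_geometry``.

    ``target_geometry`` may be any object exposing shape/spacing/origin
    (an :class:`ImageVolume` or a :class:`DoseGrid`). Voxels of the target
    whose world position falls outside the moving volume receive
    ``fill_value`` (default −1000 HU for CT-like input, 0 otherwise); if any
    such voxels exist a warning reports their fraction.
    """
    if fill_value is None:
        fill_value = _default_fill(moving)
    t_shape, t_spacing, t_origin = (
        target_geometry.shape,
        target_geometry.spacing,
        target_geometry.origin,
    )
    if co_registered(moving, target_geometry):
        return ImageVolume(
            moving.data.copy(), moving.spacing, moving.origin, moving.modality
        )
    axes = [
        (np.arange(n) * t_spacing[d] + t_origin[d] - moving.origin[d]) / moving.spacing[d]
        for d, n in enumerate(t_shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        moving.data, coords, order=1, mode="constant", cval=fill_value
    )
    outside = np.zeros(t_shape, dtype=bool)
    for d in range(3):
        ax = axes[d].reshape([-1 if i == d else 1 for i in range(3)])
        outside |= (ax < 0) | (ax > moving.shape[d] - 1)
    n_out = int(outside.sum())
    if n_out:
        warnings.warn(
            f"resample_linear: {n_out / outside.size:.1%} of target voxels fall "
            f"outside the moving volume and were filled with {fill_value}",
            stacklevel=2,
        )
    return ImageVolume(out, t_spacing, t_origin, moving.modality)


def resample_mask(
    mask: StructureMask, target_geometry, threshold: float = 0.5
) -> StructureMask:
    """Resample a binary mask onto another grid (trilinear + 0.5 threshold)."""
    if co_registered(mask, target_geometry):
        return StructureMask(mask.name, mask.role, mask.mask.copy(), mask.spacing, mask.origin)
    as_image = ImageVolume(
        mask.mask.astype(float), mask.spacing, mask.origin, Modality.MRI
    )
    res = resample_linear(as_image, target_geometry, fill_value=0.0)
    return StructureMask(
        mask.name,
        mask.role,
        res.data >= threshold,
        target_geometry.spacing,
        target_geometry.origin,
    )


def dilate_isotropic(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Euclidean dilation in world units (the PTV margining operation).

    The output contains every voxel whose center lies within ``margin_mm`` of
    a voxel center of the input set; the input is always a subset of the
    output, and a zero margin returns the input unchanged.
    """
    if margin_mm < 0:
        raise ValueError("dilate_isotropic: margin_mm must be >= 0")
    if not mask.mask.any():
        raise ValueError(f"dilate_isotropic: mask '{mask.name}' is empty")
    if margin_mm == 0:
        out = mask.mask.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
        out = dist <= margin_mm + 1e-9
    return StructureMask(mask.name, mask.role, out, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O. nibabel stores data (x, y, z); the package convention is
# (z, y, x), so arrays are transposed on the way in/out. Negative diagonal
# affine entries (e.g. LPS/RAS flips) are resolved by flipping the axis; any
# off-diagonal rotation is an unsupported oblique geometry.
# ---------------------------------------------------------------------------


def _affine_to_geometry(affine: np.ndarray, shape_xyz, path) -> tuple:
    rot = affine[:3, :3]
    for i in range(3):
        for j in range(3):
            if i != j and abs(rot[i, j]) > 1e-6 * max(1.0, abs(rot[j, j])):
                raise ValueError(
                    f"read_nifti: {path}: oblique orientation (off-diagonal affine "
                    f"element [{i},{j}]={rot[i, j]:.4g}) is unsupported; "
                    "resample to an axis-aligned grid first"
                )
    spacing_xyz, origin_xyz, flips = [], [], []
    for d in range(3):
        a = rot[d, d]
        if a == 0:
            raise ValueError(f"read_nifti: {path}: degenerate affine (zero scale on axis {d})")
        t = affine[d, 3]
        if a < 0:
            flips.append(d)
            t = t + a * (shape_xyz[d] - 1)
        spacing_xyz.append(abs(a))
        origin_xyz.append(t)
    return spacing_xyz, origin_xyz, flips


def read_nifti(
    path,
    kind: str = "image",
    modality: Modality = Modality.CT,
    name: str | None = None,
    role: StructureRole | None = None,
):
    """Read a NIfTI volume as an ImageVolume, DoseGrid or StructureMask.

    ``kind`` selects the returned type: "image", "dose" or "mask". For masks
    the ``<name>.<role>.nii[.gz]`` filename convention supplies name/role
    when they are not given explicitly.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data_xyz = np.asanyarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    except ValueError:
        raise
    except Exception as exc:  # malformed file → informative failure
        raise ValueError(f"read_nifti: cannot read {path}: {exc}") from exc
    if data_xyz.ndim != 3:
        raise ValueError(f"read_nifti: {path}: expected 3D data, got shape {data_xyz.shape}")
    spacing_xyz, origin_xyz, flips = _affine_to_geometry(affine, data_xyz.shape, path)
    for d in flips:
        data_xyz = np.flip(data_xyz, axis=d)
    data = np.ascontiguousarray(np.transpose(data_xyz, (2, 1, 0)), dtype=np.float64)
    spacing = (spacing_xyz[2], spacing_xyz[1], spacing_xyz[0])
    origin = (origin_xyz[2], origin_xyz[1], origin_xyz[0])
    if kind == "image":
        return ImageVolume(data, spacing, origin, modality)
    if kind == "dose":
        return DoseGrid(data, spacing, origin, label=path.name)
    if kind == "mask":
        stem_parts = path.name.split(".")
        if name is None:
            name = stem_parts[0]
        if role is None:
            try:
                role = StructureRole(stem_parts[1].upper())
            except (IndexError, ValueError):
                role = StructureRole.OAR
        return StructureMask(name, role, data > 0.5, spacing, origin)
    raise ValueError(f"read_nifti: unknown kind {kind!r}")


def write_nifti(obj, path) -> None:
    """Write an ImageVolume, DoseGrid or StructureMask as NIfTI-1."""
    path = Path(path)
    if isinstance(obj, ImageVolume):
        data, dtype = obj.data, np.float64
    elif isinstance(obj, DoseGrid):
        data, dtype = obj.dose, np.float64
    elif isinstance(obj, StructureMask):
        data, dtype = obj.mask.astype(np.uint8), np.uint8
    else:
        raise TypeError(f"write_nifti: unsupported object {type(obj).__name__}")
    data_xyz = np.ascontiguousarray(np.transpose(data, (2, 1, 0)).astype(dtype))
    sz, sy, sx = obj.spacing
    oz, oy, ox = obj.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    nib.save(nib.Nifti1Image(data_xyz, affine), str(path))
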