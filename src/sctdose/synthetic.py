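"""Synthetic head phantoms, SRT prescriptions, analytic dose maps and
ground-truth perturbations.

These generators stand in for patient acquisitions: a head-like CT with
air/soft-tissue/bone classes, a qualitatively T1-like MRI channel with bias
field and noise, schematic intracranial structures, and steep-gradient
stereotactic dose distributions with closed-form isodose volumes so that
every downstream metric (gamma, DVH, plan indices) can be checked against
known ground truth. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import (
    DoseGrid,
    ImageVolume,
    Modality,
    StructureMask,
    StructureRole,
    dilate_isotropic,
    require_co_registered,
)

__all__ = [
    "PhantomSpec",
    "Protocol",
    "Prescription",
    "PerturbationSpec",
    "make_head_phantom",
    "make_srt_dose",
    "perturb_dose",
    "degrade_ct",
]

DEFAULT_HU_LEVELS = {"air": -1000.0, "soft": 30.0, "bone": 700.0, "lesion": 45.0}

# MRI class intensities: soft tissue brightest, bone dark, air zero
# (qualitatively T1-like; contrast-enhancing lesion slightly brighter).
DEFAULT_MRI_LEVELS = {"air": 0.0, "soft": 1000.0, "bone": 120.0, "lesion": 1150.0}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    Grid defaults follow the 2 mm isotropic dose-calculation grid typical of
    brain SRT planning; CT phantoms may use finer spacing. ``head_radii``,
    ``lesion_centers`` and ``lesion_radii`` are in mm; lesion centers are
    world offsets from the head center. The default single 7.8 mm lesion
    dilates to a ~3.9 cm3 PTV, close to the median metastasis size treated
    with this technique.
    """

    shape: tuple[int, int, int] = (70, 96, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_radii: tuple[float, float, float] = (62.0, 88.0, 70.0)
    skull_thickness: float = 6.0
    lesion_centers: tuple = ((6.0, -24.0, 22.0),)
    lesion_radii: tuple = (7.8,)
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))
    ct_noise_sd: float = 10.0
    mri_noise_sd: float = 20.0
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.lesion_centers) != len(self.lesion_radii):
            raise ValueError("PhantomSpec: one radius per lesion center required")
        if not (self.hu_levels["bone"] > 150.0):
            raise ValueError("PhantomSpec: bone HU level must exceed 150")
        if not (-150.0 < self.hu_levels["soft"] < 150.0):
            raise ValueError("PhantomSpec: soft-tissue HU level must lie in (-150, 150)")


class Protocol(str, enum.Enum):
    PD1 = "PD1"  # homogeneous peripheral prescription
    PD2 = "PD2"  # heterogeneous, dose gradient inside the PTV


@dataclass
class Prescription:
    """An SRT prescription protocol.

    PD1 prescribes 3 x 7.7 Gy homogeneously at the PTV periphery; PD2
    prescribes 3 x 11 Gy at the isocenter with the 70% isodose covering the
    PTV. Reduced variants (3 x 7, 3 x 10) exist for cases where organ-at-risk
    constraints cannot otherwise be met.
    """

    protocol: Protocol
    fractions: int
    dose_per_fraction: float
    peripheral_isodose_fraction: float
    reference_isodose_gy: float | None = None

    def __post_init__(self):
        self.protocol = Protocol(self.protocol)
        if not (0.0 < self.peripheral_isodose_fraction <= 1.0):
            raise ValueError("Prescription: peripheral isodose fraction must be in (0, 1]")
        if self.fractions <= 0 or self.dose_per_fraction <= 0:
            raise ValueError("Prescription: fractions and dose per fraction must be positive")

    @property
    def total_dose_gy(self) -> float:
        return self.fractions * self.dose_per_fraction

    @classmethod
    def pd1(cls) -> "Prescription":
        return cls(Protocol.PD1, 3, 7.7, 1.0)

    @classmethod
    def pd2(cls) -> "Prescription":
        return cls(Protocol.PD2, 3, 11.0, 0.70)

    @classmethod
    def pd1_reduced(cls) -> "Prescription":
        return cls(Protocol.PD1, 3, 7.0, 1.0)

    @classmethod
    def pd2_reduced(cls) -> "Prescription":
        return cls(Protocol.PD2, 3, 10.0, 0.70)


@dataclass
class PerturbationSpec:
    """Controlled dose-map perturbation with known ground truth."""

    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dose_scale: float = 1.0
    noise_sd_gy: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dose_scale <= 0:
            raise ValueError("PerturbationSpec: dose_scale must be > 0")
        if self.noise_sd_gy < 0:
            raise ValueError("PerturbationSpec: noise_sd_gy must be >= 0")


# ---------------------------------------------------------------------------
# phantom construction helpers
# ---------------------------------------------------------------------------


def _world_grids(spec: PhantomSpec):
    """Per-axis world coordinates (mm) relative to the grid center."""
    out = []
    for d in range(3):
        n, s = spec.shape[d], spec.spacing[d]
        c = (n - 1) / 2.0 * s
        out.append((np.arange(n) * s - c).reshape([-1 if i == d else 1 for i in range(3)]))
    return out


def _ellipsoid(zyx, center, radii) -> np.ndarray:
    q = sum(((zyx[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    return q <= 1.0


def _sphere(zyx, center, radius) -> np.ndarray:
    return _ellipsoid(zyx, center, (radius, radius, radius))


def _cylinder_z(zyx, center, radius, half_length) -> np.ndarray:
    radial = (zyx[1] - center[1]) ** 2 + (zyx[2] - center[2]) ** 2 <= radius**2
    axial = np.abs(zyx[0] - center[0]) <= half_length
    return radial & axial


def _cylinder_y(zyx, center, radius, half_length) -> np.ndarray:
    radial = (zyx[0] - center[0]) ** 2 + (zyx[2] - center[2]) ** 2 <= radius**2
    axial = np.abs(zyx[1] - center[1]) <= half_length
    return radial & axial


def make_head_phantom(spec: PhantomSpec):
    """Build a paired CT/MRI head phantom with schematic structures.

    Returns ``(ct, mri, structures)``. The CT is piecewise-constant
    (air −1000 / soft 30 / skull 700 / lesion) plus Gaussian HU noise; the
    MRI is a monotone nonlinear map of the tissue class modulated by a
    smooth multiplicative bias field plus noise, zero outside the head.
    Structures comprise the body, brain, schematic OARs (simple geometric
    primitives at plausible offsets), one GTV per lesion and the PTV (GTV
    dilated by a 2 mm isotropic margin). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    zyx = _world_grids(spec)
    hr = spec.head_radii
    t = spec.skull_thickness

    head = _ellipsoid(zyx, (0, 0, 0), hr)
    inner = _ellipsoid(zyx, (0, 0, 0), tuple(r - t for r in hr))
    brain_radii = tuple(r - t - 4.0 for r in hr)
    brain = _ellipsoid(zyx, (0, 0, 0), brain_radii)

    hu = spec.hu_levels
    ct = np.full(spec.shape, hu["air"], dtype=np.float64)
    ct[head] = hu["bone"]
    ct[inner] = hu["soft"]

    mri_class = np.zeros(spec.shape, dtype=np.float64)
    mri_class[head] = DEFAULT_MRI_LEVELS["bone"]
    mri_class[inner] = DEFAULT_MRI_LEVELS["soft"]

    gtvs = []
    for i, (center, radius) in enumerate(zip(spec.lesion_centers, spec.lesion_radii)):
        lesion = _sphere(zyx, center, radius)
        if not lesion.any():
            raise ValueError(f"make_head_phantom: lesion {i} covers no voxel")
        if np.any(lesion & ~brain):
            raise ValueError(
                f"make_head_phantom: lesion {i} at {center} (r={radius} mm) "
                "extends outside the brain"
            )
        ct[lesion] = hu["lesion"]
        mri_class[lesion] = DEFAULT_MRI_LEVELS["lesion"]
        gtvs.append(lesion)

    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, spec.shape)

    # smooth multiplicative bias field: low-frequency cosine mixture in [-1, 1]
    phases = rng.uniform(0, 2 * np.pi, size=3)
    extent = [spec.shape[d] * spec.spacing[d] for d in range(3)]
    bias = sum(np.cos(2 * np.pi * zyx[d] / extent[d] + phases[d]) for d in range(3)) / 3.0
    mri = mri_class * (1.0 + spec.bias_field_amplitude * bias)
    if spec.mri_noise_sd > 0:
        mri = mri + rng.normal(0.0, spec.mri_noise_sd, spec.shape)
    mri[~head] = 0.0

    sp, org = spec.spacing, (0.0, 0.0, 0.0)

    def _mask(name, role, arr):
        return StructureMask(name, role, arr, sp, org)

    # schematic OARs: anterior is +y, left is +x, superior is +z
    bz, by, bx = brain_radii
    structures = [
        _mask("body", StructureRole.BODY, head),
        _mask("brain", StructureRole.OAR, brain),
        _mask(
            "brainstem",
            StructureRole.OAR,
            _cylinder_z(zyx, (-0.55 * bz, -0.15 * by, 0.0), 8.0, 0.35 * bz) & brain,
        ),
        _mask("eye_l", StructureRole.OAR, _sphere(zyx, (-0.35 * bz, 0.92 * by, 0.38 * bx), 11.0) & head),
        _mask("eye_r", StructureRole.OAR, _sphere(zyx, (-0.35 * bz, 0.92 * by, -0.38 * bx), 11.0) & head),
        _mask("lens_l", StructureRole.OAR, _sphere(zyx, (-0.35 * bz, 0.92 * by + 8.0, 0.38 * bx), 4.0) & head),
        _mask("lens_r", StructureRole.OAR, _sphere(zyx, (-0.35 * bz, 0.92 * by + 8.0, -0.38 * bx), 4.0) & head),
        _mask(
            "optic_nerve_l",
            StructureRole.OAR,
            _cylinder_y(zyx, (-0.35 * bz, 0.60 * by, 0.22 * bx), 2.5, 0.25 * by),
        ),
        _mask(
            "optic_nerve_r",
            StructureRole.OAR,
            _cylinder_y(zyx, (-0.35 * bz, 0.60 * by, -0.22 * bx), 2.5, 0.25 * by),
        ),
        _mask("chiasm", StructureRole.OAR, _sphere(zyx, (-0.35 * bz, 0.30 * by, 0.0), 4.5)),
        _mask("hypophysis", StructureRole.OAR, _sphere(zyx, (-0.48 * bz, 0.30 * by, 0.0), 4.0)),
        _mask("inner_ear_l", StructureRole.OAR, _sphere(zyx, (-0.40 * bz, -0.10 * by, 0.80 * bx), 4.5) & head),
        _mask("inner_ear_r", StructureRole.OAR, _sphere(zyx, (-0.40 * bz, -0.10 * by, -0.80 * bx), 4.5) & head),
    ]
    for i, gtv in enumerate(gtvs, start=1):
        g = _mask(f"gtv_{i}", StructureRole.GTV, gtv)
        structures.append(g)
        ptv = dilate_isotropic(g, 2.0)  # 2 mm isotropic safety margin
        ptv.name = f"ptv_{i}"
        ptv.role = StructureRole.PTV
        structures.append(ptv)

    ct_vol = ImageVolume(ct, sp, org, Modality.CT)
    mri_vol = ImageVolume(mri, sp, org, Modality.MRI)
    return ct_vol, mri_vol, structures


# ---------------------------------------------------------------------------
# analytic SRT dose
# ---------------------------------------------------------------------------


def _structure_centroid_world(mask: StructureMask) -> np.ndarray:
    idx = np.argwhere(mask.mask)
    centroid_idx = idx.mean(axis=0)
    return np.asarray(mask.origin) + centroid_idx * np.asarray(mask.spacing)


def make_srt_dose(
    structures,
    prescription: Prescription,
    geometry,
    plateau_falloff_factor: float = 1.6,
    label: str = "initial",
) -> DoseGrid:
    """Analytic steep-gradient SRT dose for each PTV, summed over lesions.

    Each PTV is reduced to its effective sphere of radius ``R``
    (``R = (3V/4pi)^(1/3)``) about its centroid. PD2 yields a Gaussian
    profile ``D(r) = D_iso * exp(-ln(1/0.7) * (r/R)^2)`` so the PTV surface
    receives exactly 70% of the isocenter dose; PD1 yields a plateau at the
    prescribed dose for ``r <= R`` with a Gaussian falloff reaching half the
    prescription at ``r = G*R`` (``G = plateau_falloff_factor``). Multiple
    lesions combine by voxelwise superposition.
    """
    ptvs = [s for s in structures if s.role == StructureRole.PTV]
    if not ptvs:
        raise ValueError("make_srt_dose: at least one PTV structure is required")
    shape, spacing, origin = geometry.shape, geometry.spacing, geometry.origin
    axes = [
        (np.arange(shape[d]) * spacing[d] + origin[d]).reshape(
            [-1 if i == d else 1 for i in range(3)]
        )
        for d in range(3)
    ]
    dose = np.zeros(shape, dtype=np.float64)
    for ptv in ptvs:
        if not ptv.mask.any():
            raise ValueError(f"make_srt_dose: PTV '{ptv.name}' is empty")
        center = _structure_centroid_world(ptv)
        volume_mm3 = float(ptv.mask.sum()) * float(np.prod(ptv.spacing))
        radius = (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        r2 = sum((axes[d] - center[d]) ** 2 for d in range(3))
        if prescription.protocol == Protocol.PD2:
            d_iso = prescription.total_dose_gy
            k = math.log(1.0 / prescription.peripheral_isodose_fraction)
            dose += d_iso * np.exp(-k * r2 / radius**2)
        else:
            pd = prescription.total_dose_gy
            r = np.sqrt(r2)
            sigma = radius * (plateau_falloff_factor - 1.0)
            lesion_dose = np.where(
                r <= radius,
                pd,
                pd * np.exp(-math.log(2.0) * ((r - radius) / sigma) ** 2),
            )
            dose += lesion_dose
    return DoseGrid(np.clip(dose, 0.0, None), spacing, origin, label=label)


def perturb_dose(dose: DoseGrid, spec: PerturbationSpec) -> DoseGrid:
    """Translate, rescale and add noise to a dose map on its own grid.

    The output at world position x samples the input at x − shift (trilinear,
    edge values extended), then is multiplied by ``dose_scale`` and receives
    Gaussian noise of ``noise_sd_gy``; negative values are clipped to zero.
    Deterministic given ``spec.seed``.
    """
    from scipy import ndimage

    extent = [dose.shape[d] * dose.spacing[d] for d in range(3)]
    for d in range(3):
        if abs(spec.shift_mm[d]) > extent[d]:
            raise ValueError(
                f"perturb_dose: shift {spec.shift_mm[d]} mm exceeds the grid "
                f"extent {extent[d]} mm on axis {d}"
            )
    if any(spec.shift_mm):
        shift_idx = [spec.shift_mm[d] / dose.spacing[d] for d in range(3)]
        coords = np.meshgrid(
            *[np.arange(n, dtype=float) - shift_idx[d] for d, n in enumerate(dose.shape)],
            indexing="ij",
        )
        out = ndimage.map_coordinates(dose.dose, coords, order=1, mode="nearest")
    else:
        out = dose.dose.copy()
    out *= spec.dose_scale
    if spec.noise_sd_gy > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sd_gy, dose.shape)
    return dose.with_dose(np.clip(out, 0.0, None), label="synthetic")


def degrade_ct(
    ct: ImageVolume, hu_bias: float, hu_noise_sd: float, seed: int = 0
) -> ImageVolume:
    """Emulate pseudo-CT error: constant HU bias plus Gaussian HU noise.

    The expected RMSE against the original over any mask is
    ``sqrt(bias^2 + sd^2)``, which makes the image-comparison metrics
    testable against known ground truth.
    """
    if not ct.is_ct_like():
        raise ValueError("degrade_ct: input must be CT-like")
    rng = np.random.default_rng(seed)
    data = ct.data + hu_bias
    if hu_noise_sd > 0:
        data = data + rng.normal(0.0, hu_noise_sd, ct.shape)
    return ImageVolume(data, ct.spacing, ct.origin, Modality.PSEUDO_CT)
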