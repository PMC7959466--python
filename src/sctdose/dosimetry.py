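"""DVH extraction, ICRU-91-style dose endpoints, plan-quality indices,
reference-isodose volumes and organ-at-risk constraint checks.

Conventions:

* Dx% is the largest dose d such that at least x% of the structure volume
  receives >= d, computed by exact order statistics on voxel doses (no
  binning); ties break toward the higher dose.
* Vx Gy is the structure volume (cm3, and % of structure volume) receiving
  >= x Gy, with binary voxel membership.
* Dmax is the maximum voxel dose (near-max alternatives such as D0.035cc
  are derivable from Dx% but not reported by default).
* The conformity index uses the Paddick-inverse form
  CI = (V_PTV * V_PIV) / V_overlap^2, which is >= 1 with equality iff the
  prescription isodose volume coincides with the PTV; the plain ratio
  V_PIV / V_PTV is exposed separately as ``coverage_ratio``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid, StructureMask, require_co_registered
from .synthetic import Prescription, Protocol

__all__ = [
    "DvhCurve",
    "DoseEndpoints",
    "PlanIndices",
    "OarConstraint",
    "ConstraintResult",
    "DEFAULT_OAR_CONSTRAINTS",
    "compute_dvh",
    "endpoints",
    "dose_at_volume_percent",
    "homogeneity_indices",
    "conformity_index",
    "coverage_ratio",
    "gradient_index",
    "isodose_volume",
    "reference_isodose",
    "plan_indices",
    "check_oar_constraints",
]

DVH_BIN_WIDTH_GY = 0.01


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    require_co_registered(dose, mask, "DVH computation")
    if not mask.mask.any():
        raise ValueError(f"structure '{mask.name}' is empty")
    return dose.dose[mask.mask]


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram for one structure.

    ``cumulative_volume_fraction[i]`` is the fraction of the structure
    receiving at least ``dose_bins[i]`` Gy; it is 1 at 0 Gy, nonincreasing,
    and 0 above the maximum structure dose.
    """

    structure: str
    dose_bins: np.ndarray
    cumulative_volume_fraction: np.ndarray
    voxel_volume_cm3: float

    def volume_fraction_at(self, dose_gy: float) -> float:
        idx = np.searchsorted(self.dose_bins, dose_gy, side="left")
        if idx >= len(self.dose_bins):
            return 0.0
        return float(self.cumulative_volume_fraction[idx])


@dataclass
class DoseEndpoints:
    """ICRU-91-style endpoint set for one structure under one dose map."""

    structure: str
    volume_cm3: float
    dmin_gy: float
    dmax_gy: float
    dmean_gy: float
    d2_gy: float
    d50_gy: float
    d98_gy: float
    vx: dict = field(default_factory=dict)  # threshold Gy -> (cm3, % of structure)


@dataclass
class PlanIndices:
    """Plan-quality indices for one PTV/plan."""

    hi1: float
    hi2: float
    hi3: float
    conformity_index: float
    gradient_index: float
    piv_cm3: float
    half_piv_cm3: float


@dataclass
class OarConstraint:
    structure: str
    metric: str  # "Dmax" or "VxGy"
    threshold: float
    unit: str  # "Gy", "cm3" or "%"
    tier: str = "primary"  # or "secondary"
    x_gy: float | None = None  # dose level for VxGy constraints
    inclusive: bool = False  # True for "<=" comparisons

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("OarConstraint: threshold must be > 0")
        if self.metric not in ("Dmax", "VxGy"):
            raise ValueError(f"OarConstraint: unknown metric {self.metric!r}")
        if self.metric == "VxGy" and self.x_gy is None:
            raise ValueError("OarConstraint: VxGy constraint requires x_gy")


@dataclass
class ConstraintResult:
    constraint: OarConstraint
    structure_name: str | None
    observed: float | None
    passed: bool | None  # None when not evaluable

    @property
    def evaluable(self) -> bool:
        return self.observed is not None


#: Clinical OAR constraint table: primary goals, with secondary fallbacks
#: where primary goals cannot be achieved.
DEFAULT_OAR_CONSTRAINTS = [
    OarConstraint("optic_nerve", "Dmax", 13.8, "Gy", "primary"),
    OarConstraint("optic_nerve", "Dmax", 17.4, "Gy", "secondary", inclusive=True),
    OarConstraint("optic_nerve", "VxGy", 0.2, "cm3", "secondary", x_gy=15.3),
    OarConstraint("chiasm", "Dmax", 10.5, "Gy", "primary"),
    OarConstraint("brainstem", "Dmax", 16.8, "Gy", "primary"),
    OarConstraint("brainstem", "Dmax", 23.1, "Gy", "secondary", inclusive=True),
    OarConstraint("brainstem", "VxGy", 0.5, "cm3", "secondary", x_gy=18.0),
    OarConstraint("brain", "VxGy", 5.0, "%", "primary", x_gy=10.0),
    OarConstraint("brain", "VxGy", 20.9, "cm3", "primary", x_gy=21.0),
]


def compute_dvh(dose: DoseGrid, mask: StructureMask) -> DvhCurve:
    """Cumulative DVH (0.01 Gy bins from 0 to the global dose maximum)."""
    doses = _mask_doses(dose, mask)
    top = float(dose.dose.max())
    bins = np.arange(0.0, top + 2 * DVH_BIN_WIDTH_GY, DVH_BIN_WIDTH_GY)
    sorted_doses = np.sort(doses)
    # fraction receiving >= bin edge
    frac = 1.0 - np.searchsorted(sorted_doses, bins, side="left") / doses.size
    return DvhCurve(
        structure=mask.name,
        dose_bins=bins,
        cumulative_volume_fraction=frac,
        voxel_volume_cm3=mask.voxel_volume_cm3,
    )


def dose_at_volume_percent(doses: np.ndarray, x_percent: float) -> float:
    """Dx%: largest dose d with >= x% of the voxels receiving >= d."""
    if not (0.0 < x_percent < 100.0):
        raise ValueError(f"Dx%: x must lie in (0, 100), got {x_percent}")
    ds = np.sort(np.asarray(doses, dtype=float))[::-1]
    k = math.ceil(x_percent / 100.0 * ds.size)  # need at least k voxels >= d
    return float(ds[k - 1])


def endpoints(
    dose: DoseGrid,
    mask: StructureMask,
    vx_thresholds_gy: tuple = (),
    dx_percents: tuple = (2.0, 50.0, 98.0),
) -> DoseEndpoints:
    """Dmin/Dmax/Dmean, Dx% by order statistics, and Vx Gy volumes."""
    doses = _mask_doses(dose, mask)
    dx = {x: dose_at_volume_percent(doses, x) for x in dx_percents}
    vv = mask.voxel_volume_cm3
    vx = {}
    for thr in vx_thresholds_gy:
        n_above = int((doses >= thr).sum())
        vx[float(thr)] = (n_above * vv, 100.0 * n_above / doses.size)
    return DoseEndpoints(
        structure=mask.name,
        volume_cm3=doses.size * vv,
        dmin_gy=float(doses.min()),
        dmax_gy=float(doses.max()),
        dmean_gy=float(doses.mean()),
        d2_gy=dx.get(2.0, float("nan")),
        d50_gy=dx.get(50.0, float("nan")),
        d98_gy=dx.get(98.0, float("nan")),
        vx=vx,
    )


def homogeneity_indices(ep: DoseEndpoints, prescription) -> tuple[float, float, float]:
    """HI1 = Dmax/PD, HI2 = (D2 − D98)/PD, HI3 = (D2 − D98)/D50.

    ``prescription`` may be a :class:`Prescription` (PD = total prescribed
    dose) or the prescribed dose in Gy directly.
    """
    pd_gy = (
        prescription.total_dose_gy
        if isinstance(prescription, Prescription)
        else float(prescription)
    )
    if pd_gy <= 0:
        raise ValueError("homogeneity_indices: prescribed dose must be > 0")
    hi1 = ep.dmax_gy / pd_gy
    hi2 = (ep.d2_gy - ep.d98_gy) / pd_gy
    if ep.d50_gy == 0:
        raise ValueError("homogeneity_indices: D50 = 0, HI3 undefined")
    hi3 = (ep.d2_gy - ep.d98_gy) / ep.d50_gy
    return (hi1, hi2, hi3)


def isodose_volume(dose: DoseGrid, level_gy: float) -> float:
    """Volume (cm3) of the region receiving >= level_gy."""
    return float((dose.dose >= level_gy).sum()) * dose.voxel_volume_cm3


def conformity_index(
    dose: DoseGrid, ptv_mask: StructureMask, reference_isodose_gy: float
) -> float:
    """Paddick-inverse conformity: (V_PTV × V_PIV) / V_overlap²; >= 1."""
    require_co_registered(dose, ptv_mask, "conformity_index")
    if not ptv_mask.mask.any():
        raise ValueError("conformity_index: PTV is empty")
    piv = dose.dose >= reference_isodose_gy
    n_piv = int(piv.sum())
    if n_piv == 0:
        raise ValueError("conformity_index: no voxel reaches the reference isodose")
    n_ptv = int(ptv_mask.mask.sum())
    n_overlap = int((piv & ptv_mask.mask).sum())
    if n_overlap == 0:
        raise ValueError(
            "conformity_index: prescription isodose volume does not intersect the PTV"
        )
    return (n_ptv * n_piv) / n_overlap**2


def coverage_ratio(
    dose: DoseGrid, ptv_mask: StructureMask, reference_isodose_gy: float
) -> float:
    """Plain prescription-isodose to PTV volume ratio V_PIV / V_PTV."""
    require_co_registered(dose, ptv_mask, "coverage_ratio")
    n_ptv = int(ptv_mask.mask.sum())
    if n_ptv == 0:
        raise ValueError("coverage_ratio: PTV is empty")
    return float((dose.dose >= reference_isodose_gy).sum()) / n_ptv


def gradient_index(dose: DoseGrid, reference_isodose_gy: float) -> float:
    """GI = V(reference/2) / V(reference); > 1 for any finite falloff."""
    v_ref = isodose_volume(dose, reference_isodose_gy)
    if v_ref == 0:
        raise ValueError("gradient_index: reference isodose volume is empty")
    return isodose_volume(dose, reference_isodose_gy / 2.0) / v_ref


def reference_isodose(prescription: Prescription) -> float:
    """Reference isodose level (Gy) anchoring PIV, CI and GI.

    23.1 Gy for the standard protocols (3 × 7.7 Gy peripheral; 3 × 11 Gy at
    isocenter with 70% peripheral isodose), 21 Gy for the reduced protocols
    (3 × 7 Gy and 3 × 10 Gy).
    """
    key = (prescription.fractions, round(prescription.dose_per_fraction, 3))
    if key == (3, 7.7) and prescription.protocol == Protocol.PD1:
        return 23.1
    if key == (3, 11.0) and prescription.protocol == Protocol.PD2:
        return round(
            prescription.peripheral_isodose_fraction * prescription.total_dose_gy, 10
        )  # 0.70 × 33 = 23.1
    if key in ((3, 7.0), (3, 10.0)):
        return 21.0
    raise ValueError(
        f"reference_isodose: unrecognized protocol {prescription.protocol} "
        f"{prescription.fractions} × {prescription.dose_per_fraction} Gy"
    )


def plan_indices(
    dose: DoseGrid, ptv_mask: StructureMask, prescription: Prescription
) -> PlanIndices:
    """All plan-quality indices for one PTV under one dose map."""
    ref = reference_isodose(prescription)
    ep = endpoints(dose, ptv_mask)
    hi1, hi2, hi3 = homogeneity_indices(ep, prescription)
    return PlanIndices(
        hi1=hi1,
        hi2=hi2,
        hi3=hi3,
        conformity_index=conformity_index(dose, ptv_mask, ref),
        gradient_index=gradient_index(dose, ref),
        piv_cm3=isodose_volume(dose, ref),
        half_piv_cm3=isodose_volume(dose, ref / 2.0),
    )


def check_oar_constraints(
    dose: DoseGrid, structures, constraint_table=None
) -> list[ConstraintResult]:
    """Evaluate the OAR constraint table against a dose map.

    ``structures`` is an iterable of StructureMask. Constraint structure
    names match by prefix so that paired organs (``optic_nerve`` →
    ``optic_nerve_l``/``_r``) are each evaluated. A constrained structure
    that is absent is reported as not evaluable, never silently passed.
    """
    if constraint_table is None:
        constraint_table = DEFAULT_OAR_CONSTRAINTS
    by_name = {s.name: s for s in structures}
    results: list[ConstraintResult] = []
    for con in constraint_table:
        matches = [
            s for name, s in sorted(by_name.items())
            if name == con.structure or name.startswith(con.structure + "_")
        ]
        if not matches:
            results.append(ConstraintResult(con, None, None, None))
            continue
        for s in matches:
            doses = _mask_doses(dose, s)
            if con.metric == "Dmax":
                observed = float(doses.max())
            else:
                n_above = int((doses >= con.x_gy).sum())
                if con.unit == "%":
                    observed = 100.0 * n_above / doses.size
                else:
                    observed = n_above * s.voxel_volume_cm3
            passed = observed <= con.threshold if con.inclusive else observed < con.threshold
            results.append(ConstraintResult(con, s.name, observed, bool(passed)))
    return results
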