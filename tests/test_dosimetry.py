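import numpy as np
import pytest

from sctdose import dosimetry
from sctdose.dosimetry import (
    OarConstraint,
    check_oar_constraints,
    compute_dvh,
    conformity_index,
    coverage_ratio,
    dose_at_volume_percent,
    endpoints,
    gradient_index,
    homogeneity_indices,
    isodose_volume,
    reference_isodose,
)
from sctdose.grids import DoseGrid, StructureMask, StructureRole
from sctdose.synthetic import Prescription, Protocol


def _grid(values, spacing=(1, 1, 1)):
    return DoseGrid(np.asarray(values, float), spacing)


def _mask(shape, where=None, spacing=(1, 1, 1), role=StructureRole.PTV, name="s"):
    m = np.zeros(shape, bool)
    if where is None:
        m[:] = True
    else:
        m[where] = True
    return StructureMask(name, role, m, spacing)


def _oracle_dx(doses, x):
    """Brute force: largest dose with >= x% of voxels receiving >= it."""
    best = None
    for d in sorted(doses):
        if 100.0 * np.sum(np.asarray(doses) >= d) / len(doses) >= x:
            best = d
    return best


class TestDvh:
    def test_uniform_dose_step_function(self):
        dose = _grid(np.full((4, 4, 4), 20.0))
        curve = compute_dvh(dose, _mask((4, 4, 4)))
        assert curve.volume_fraction_at(0.0) == 1.0
        assert curve.volume_fraction_at(19.99) == 1.0
        assert curve.volume_fraction_at(20.01) == 0.0

    def test_two_level_dose(self):
        data = np.full((2, 4, 4), 10.0)
        data[1] = 30.0
        curve = compute_dvh(_grid(data), _mask((2, 4, 4)))
        assert curve.volume_fraction_at(20.0) == pytest.approx(0.5)
        assert curve.volume_fraction_at(10.0) == pytest.approx(1.0)

    def test_linear_ramp_closed_form(self):
        n = 400
        dose = _grid(np.linspace(0, 40, n).reshape(1, 1, n))
        curve = compute_dvh(dose, _mask((1, 1, n)))
        for d in (5.0, 21.0, 33.0):
            assert curve.volume_fraction_at(d) == pytest.approx(1 - d / 40, abs=0.01)

    def test_nonincreasing(self, pd2_dose, phantom):
        _, _, structures = phantom
        ptv = next(s for s in structures if s.role == StructureRole.PTV)
        curve = compute_dvh(pd2_dose, ptv)
        assert np.all(np.diff(curve.cumulative_volume_fraction) <= 1e-12)

    def test_empty_mask_rejected(self, pd2_dose):
        empty = _mask(pd2_dose.shape, where=(slice(0, 0),), spacing=pd2_dose.spacing)
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(pd2_dose, empty)


class TestEndpoints:
    def test_uniform_dose_collapses_all_endpoints(self):
        dose = _grid(np.full((4, 4, 4), 20.0))
        ep = endpoints(dose, _mask((4, 4, 4)))
        for v in (ep.dmin_gy, ep.dmax_gy, ep.dmean_gy, ep.d2_gy, ep.d50_gy, ep.d98_gy):
            assert v == pytest.approx(20.0)

    def test_order_statistics_on_1_to_100(self):
        doses = np.arange(1.0, 101.0).reshape(1, 10, 10)
        ep = endpoints(_grid(doses), _mask((1, 10, 10)))
        assert ep.d2_gy == 99.0
        assert ep.d50_gy == 51.0
        assert ep.d98_gy == 3.0
        # brute-force oracle agreement on arbitrary percentiles
        flat = doses.ravel()
        for x in (2, 11, 37, 50, 76.5, 98):
            assert dose_at_volume_percent(flat, x) == _oracle_dx(flat, x)

    def test_v21_of_ramp_closed_form(self):
        n = 400
        dose = _grid(np.linspace(0, 40, n).reshape(1, 1, n))
        ep = endpoints(dose, _mask((1, 1, n)), vx_thresholds_gy=(21.0,))
        _, pct = ep.vx[21.0]
        assert pct == pytest.approx(100 * (40 - 21) / 40, abs=100 / n)

    def test_endpoint_ordering_invariant_on_random_fields(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            doses = rng.gamma(2.0, 5.0, size=rng.integers(5, 200))
            d2 = dose_at_volume_percent(doses, 2)
            d50 = dose_at_volume_percent(doses, 50)
            d98 = dose_at_volume_percent(doses, 98)
            assert doses.min() <= d98 <= d50 <= d2 <= doses.max()

    def test_dvh_consistent_with_endpoints(self):
        # distinct-valued dose: the curve evaluated at Dx% recovers x/100
        # within one bin width; radially symmetric doses are excluded here
        # because their massive dose ties make the step unresolvable at any
        # bin width (the bracketing check below covers that case)
        rng = np.random.default_rng(9)
        dose = _grid(rng.uniform(20.0, 33.0, (8, 8, 8)))
        mask = _mask((8, 8, 8))
        curve = compute_dvh(dose, mask)
        ep = endpoints(dose, mask)
        for x, d in ((2, ep.d2_gy), (50, ep.d50_gy), (98, ep.d98_gy)):
            assert curve.volume_fraction_at(d) == pytest.approx(x / 100, abs=0.02)

    def test_dvh_brackets_endpoints_under_ties(self, pd2_dose, phantom):
        _, _, structures = phantom
        ptv = next(s for s in structures if s.role == StructureRole.PTV)
        curve = compute_dvh(pd2_dose, ptv)
        ep = endpoints(pd2_dose, ptv)
        # at least 50% receives >= D50, so the curve one bin below D50 is >= 0.5
        assert curve.volume_fraction_at(ep.d50_gy - 0.011) >= 0.5

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            dose_at_volume_percent(np.ones(10), 0.0)


class TestIndices:
    def test_homogeneity_uniform_dose(self):
        dose = _grid(np.full((4, 4, 4), 23.1))
        ep = endpoints(dose, _mask((4, 4, 4)))
        hi1, hi2, hi3 = homogeneity_indices(ep, 23.1)
        assert (hi1, hi2, hi3) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(0.0))

    def test_homogeneity_arithmetic(self):
        ep = dosimetry.DoseEndpoints("ptv", 1.0, 20.0, 24.7, 22.0, 30.0, 27.0, 24.0)
        hi1, hi2, hi3 = homogeneity_indices(ep, Prescription.pd1())
        assert hi1 == pytest.approx(24.7 / 23.1)
        assert hi2 == pytest.approx(6.0 / 23.1)
        assert hi3 == pytest.approx(6.0 / 27.0)

    def test_conformity_perfect_is_one(self):
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 30.0
        dose = _grid(data)
        ptv = _mask((6, 6, 6), where=(slice(2, 4), slice(2, 4), slice(2, 4)))
        assert conformity_index(dose, ptv, 23.1) == pytest.approx(1.0)

    def test_conformity_4_8_4(self):
        # V_PTV = 4 cm3 fully covered by an 8 cm3 PIV -> CI = 4*8/4^2 = 2
        data = np.zeros((8, 8, 8))
        data[0:2, 0:2, 0:2] = 30.0  # 8 voxels of 1 cm3 at 10 mm spacing
        dose = _grid(data, spacing=(10, 10, 10))
        ptv = _mask((8, 8, 8), where=(slice(0, 1), slice(0, 2), slice(0, 2)),
                    spacing=(10, 10, 10))
        assert conformity_index(dose, ptv, 23.1) == pytest.approx(2.0)
        assert coverage_ratio(dose, ptv, 23.1) == pytest.approx(2.0)

    def test_conformity_monotone_in_piv_shrinkage(self):
        # shrinking the PIV below full PTV coverage strictly increases CI
        data = np.zeros((8, 8, 8))
        data[2:6, 2:6, 2:6] = 25.0
        data[3:5, 3:5, 3:5] = 30.0
        dose = _grid(data)
        ptv = _mask((8, 8, 8), where=(slice(2, 6), slice(2, 6), slice(2, 6)))
        ci_wide = conformity_index(dose, ptv, 24.0)  # PIV = 64 voxels
        ci_tight = conformity_index(dose, ptv, 28.0)  # PIV = 8 voxels inside PTV
        assert ci_tight > ci_wide >= 1.0

    def test_gradient_index_degenerate_bound(self):
        dose = _grid(np.full((4, 4, 4), 30.0))
        assert gradient_index(dose, 23.1) == pytest.approx(1.0)

    def test_isodose_volume_nonincreasing(self, pd2_dose):
        levels = np.linspace(1, 30, 15)
        vols = [isodose_volume(pd2_dose, lv) for lv in levels]
        assert np.all(np.diff(vols) <= 0)

    def test_gi_and_ci_invariant_under_joint_rescaling(self, pd2_dose, phantom):
        _, _, structures = phantom
        ptv = next(s for s in structures if s.role == StructureRole.PTV)
        scaled = pd2_dose.with_dose(2.0 * pd2_dose.dose)
        assert gradient_index(pd2_dose, 23.1) == pytest.approx(
            gradient_index(scaled, 46.2))
        assert conformity_index(pd2_dose, ptv, 23.1) == pytest.approx(
            conformity_index(scaled, ptv, 46.2))


class TestReferenceIsodose:
    def test_standard_protocols(self):
        assert reference_isodose(Prescription.pd1()) == pytest.approx(23.1)
        assert reference_isodose(Prescription.pd2()) == pytest.approx(23.1)

    def test_reduced_protocols(self):
        assert reference_isodose(Prescription.pd1_reduced()) == 21.0
        assert reference_isodose(Prescription.pd2_reduced()) == 21.0

    def test_unknown_protocol_rejected(self):
        odd = Prescription(Protocol.PD1, 5, 4.0, 1.0)
        with pytest.raises(ValueError, match="unrecognized"):
            reference_isodose(odd)


class TestOarConstraints:
    def _structures(self, shape=(4, 4, 4)):
        return [
            _mask(shape, name="brainstem", role=StructureRole.OAR),
            _mask(shape, name="brain", role=StructureRole.OAR),
        ]

    def test_zero_dose_passes_everything(self):
        dose = _grid(np.zeros((4, 4, 4)))
        results = check_oar_constraints(dose, self._structures())
        evaluable = [r for r in results if r.evaluable]
        assert evaluable and all(r.passed for r in evaluable)

    def test_brainstem_primary_fails_secondary_passes(self):
        dose = _grid(np.full((4, 4, 4), 17.0))
        results = check_oar_constraints(dose, self._structures())
        by = {(r.constraint.structure, r.constraint.metric, r.constraint.tier): r
              for r in results if r.structure_name == "brainstem"}
        assert by[("brainstem", "Dmax", "primary")].passed is False  # < 16.8
        assert by[("brainstem", "Dmax", "secondary")].passed is True  # <= 23.1

    def test_brain_v10_percent_violation(self):
        data = np.zeros((10, 10, 10))
        data[:, :, :1] = 12.0  # 10% of the brain >= 10 Gy, limit is < 5%
        brain = _mask((10, 10, 10), name="brain", role=StructureRole.OAR)
        results = check_oar_constraints(_grid(data), [brain])
        v10 = next(r for r in results
                   if r.structure_name == "brain" and r.constraint.x_gy == 10.0)
        assert v10.passed is False
        assert v10.observed == pytest.approx(10.0)

    def test_missing_structure_flagged_not_evaluable(self):
        dose = _grid(np.zeros((4, 4, 4)))
        results = check_oar_constraints(dose, [])
        assert results and all(not r.evaluable for r in results)

    def test_paired_organs_match_by_prefix(self):
        shape = (4, 4, 4)
        structures = [
            _mask(shape, name="optic_nerve_l", role=StructureRole.OAR),
            _mask(shape, name="optic_nerve_r", role=StructureRole.OAR),
        ]
        dose = _grid(np.full(shape, 14.0))
        results = [r for r in check_oar_constraints(dose, structures)
                   if r.constraint.structure == "optic_nerve"
                   and r.constraint.metric == "Dmax" and r.constraint.tier == "primary"]
        assert {r.structure_name for r in results} == {"optic_nerve_l", "optic_nerve_r"}
        assert all(r.passed is False for r in results)  # 14 Gy >= 13.8 Gy limit

    def test_invalid_constraint_rejected(self):
        with pytest.raises(ValueError, match="x_gy"):
            OarConstraint("brain", "VxGy", 5.0, "%")
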