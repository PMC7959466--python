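import math

import numpy as np
import pytest

from sctdose.grids import Modality, StructureRole
from sctdose.synthetic import (
    PerturbationSpec,
    PhantomSpec,
    Prescription,
    Protocol,
    degrade_ct,
    make_head_phantom,
    make_srt_dose,
    perturb_dose,
)
from sctdose.grids import DoseGrid, ImageVolume, StructureMask


class TestHeadPhantom:
    def test_air_outside_head(self, noise_free_phantom):
        ct, _, structures = noise_free_phantom
        body = next(s for s in structures if s.role == StructureRole.BODY)
        assert np.all(ct.data[~body.mask] == -1000.0)

    def test_skull_is_bone_class(self, noise_free_phantom):
        ct, _, _ = noise_free_phantom
        skull = ct.data == 700.0
        assert skull.any()
        assert np.all(ct.data[skull] > 150.0)  # bone-class threshold

    def test_determinism(self):
        spec = PhantomSpec(seed=3)
        ct1, mri1, _ = make_head_phantom(spec)
        ct2, mri2, _ = make_head_phantom(spec)
        np.testing.assert_array_equal(ct1.data, ct2.data)
        np.testing.assert_array_equal(mri1.data, mri2.data)

    def test_mri_zero_outside_head(self, phantom):
        _, mri, structures = phantom
        body = next(s for s in structures if s.role == StructureRole.BODY)
        assert np.all(mri.data[~body.mask] == 0.0)

    def test_lesion_outside_brain_rejected(self):
        # lesion straddling the brain boundary
        spec = PhantomSpec(lesion_centers=((0.0, 0.0, 58.0),), lesion_radii=(5.0,))
        with pytest.raises(ValueError, match="outside the brain"):
            make_head_phantom(spec)
        # lesion entirely off the grid
        spec = PhantomSpec(lesion_centers=((0.0, 0.0, 1000.0),), lesion_radii=(5.0,))
        with pytest.raises(ValueError, match="no voxel"):
            make_head_phantom(spec)

    def test_expected_structures_present(self, phantom):
        _, _, structures = phantom
        names = {s.name for s in structures}
        assert {"body", "brain", "brainstem", "chiasm", "hypophysis",
                "eye_l", "eye_r", "lens_l", "lens_r", "optic_nerve_l",
                "optic_nerve_r", "inner_ear_l", "inner_ear_r",
                "gtv_1", "ptv_1"} <= names
        ptv = next(s for s in structures if s.name == "ptv_1")
        gtv = next(s for s in structures if s.name == "gtv_1")
        assert np.all(ptv.mask[gtv.mask])  # PTV contains its GTV

    def test_class_volumes_converge_with_spacing(self):
        # halving the spacing changes the estimated bone volume by < 2%
        coarse = PhantomSpec(shape=(70, 96, 80), spacing=(2.0, 2.0, 2.0),
                             ct_noise_sd=0.0, mri_noise_sd=0.0)
        fine = PhantomSpec(shape=(140, 192, 160), spacing=(1.0, 1.0, 1.0),
                           ct_noise_sd=0.0, mri_noise_sd=0.0)
        v = []
        for spec in (coarse, fine):
            ct, _, _ = make_head_phantom(spec)
            v.append((ct.data == 700.0).sum() * np.prod(spec.spacing))
        assert abs(v[0] - v[1]) / v[1] < 0.02


class TestPrescription:
    def test_total_dose(self):
        assert Prescription.pd1().total_dose_gy == pytest.approx(23.1)
        assert Prescription.pd2().total_dose_gy == pytest.approx(33.0)

    def test_pd2_peripheral_fraction(self):
        assert Prescription.pd2().peripheral_isodose_fraction == 0.70

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            Prescription(Protocol.PD2, 3, 11.0, 1.5)


def _sphere_ptv(radius_mm=9.8, n=40, spacing=1.5):
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = z**2 + y**2 + x**2 <= radius_mm**2
    return StructureMask("ptv_1", StructureRole.PTV, mask, (spacing,) * 3)


class TestSrtDose:
    def test_pd2_isocenter_and_surface(self):
        ptv = _sphere_ptv(n=41)  # odd grid: centroid falls on a voxel center
        geometry = ImageVolume(np.zeros(ptv.shape), ptv.spacing)
        dose = make_srt_dose([ptv], Prescription.pd2(), geometry)
        center = tuple(s // 2 for s in ptv.shape)
        assert dose.dose[center] == pytest.approx(33.0, rel=1e-9)
        # dose at the PTV effective radius is the 70% peripheral isodose
        r_eff = (3 * ptv.mask.sum() * np.prod(ptv.spacing) / (4 * math.pi)) ** (1 / 3)
        k = math.log(1 / 0.7)
        sampled = 33.0 * math.exp(-k)  # analytic value at r = R
        assert sampled == pytest.approx(23.1, rel=1e-9)
        # voxels closest to the surface are near 23.1 Gy
        ax = (np.arange(41) - 20) * 1.5
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(z**2 + y**2 + x**2)
        shell = np.abs(r - r_eff) < 0.75
        assert np.allclose(dose.dose[shell], 23.1, rtol=0.06)

    def test_pd1_plateau_and_half_dose_radius(self):
        ptv = _sphere_ptv(n=41)
        geometry = ImageVolume(np.zeros(ptv.shape), ptv.spacing)
        dose = make_srt_dose([ptv], Prescription.pd1(), geometry, plateau_falloff_factor=1.6)
        r_eff = (3 * ptv.mask.sum() * np.prod(ptv.spacing) / (4 * math.pi)) ** (1 / 3)
        ax = (np.arange(41) - 20) * 1.5
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(z**2 + y**2 + x**2)
        assert np.allclose(dose.dose[r <= r_eff - 1.0], 23.1)
        # the half-prescription crossing along the +x axis sits at G*R
        profile = dose.dose[20, 20, 20:]
        radii = ax[20:]
        r_cross = np.interp(-0.5 * 23.1, -profile, radii)  # profile decreasing
        assert r_cross == pytest.approx(1.6 * r_eff, abs=ptv.spacing[2])

    def test_superposition_of_lesions(self):
        spec = PhantomSpec(
            lesion_centers=((0.0, -24.0, 22.0), (0.0, 20.0, -20.0)),
            lesion_radii=(7.8, 6.0),
            ct_noise_sd=0.0, mri_noise_sd=0.0,
        )
        ct, _, structures = make_head_phantom(spec)
        ptvs = [s for s in structures if s.role == StructureRole.PTV]
        both = make_srt_dose(ptvs, Prescription.pd2(), ct)
        single = [make_srt_dose([p], Prescription.pd2(), ct) for p in ptvs]
        np.testing.assert_allclose(
            both.dose, single[0].dose + single[1].dose, atol=1e-12
        )

    def test_missing_ptv_rejected(self):
        geometry = ImageVolume(np.zeros((8, 8, 8)), (2, 2, 2))
        with pytest.raises(ValueError, match="PTV"):
            make_srt_dose([], Prescription.pd2(), geometry)


class TestPerturbDose:
    def test_identity_spec(self, pd2_dose):
        out = perturb_dose(pd2_dose, PerturbationSpec())
        np.testing.assert_array_equal(out.dose, pd2_dose.dose)

    def test_pure_scaling(self, pd2_dose):
        out = perturb_dose(pd2_dose, PerturbationSpec(dose_scale=1.01))
        np.testing.assert_allclose(out.dose, 1.01 * pd2_dose.dose, rtol=1e-12)

    def test_shift_of_linear_ramp(self):
        # 1 Gy/mm ramp shifted 1 mm along x -> interior difference of 1 Gy
        x = np.arange(20) * 1.0
        ramp = DoseGrid(np.broadcast_to(10.0 + x, (6, 6, 20)).copy(), (1, 1, 1))
        out = perturb_dose(ramp, PerturbationSpec(shift_mm=(0, 0, 1.0)))
        diff = ramp.dose[:, :, 2:-2] - out.dose[:, :, 2:-2]
        np.testing.assert_allclose(diff, 1.0, atol=1e-12)

    def test_excessive_shift_rejected(self, pd2_dose):
        with pytest.raises(ValueError, match="exceeds"):
            perturb_dose(pd2_dose, PerturbationSpec(shift_mm=(0, 0, 1e4)))

    def test_noise_determinism(self, pd2_dose):
        spec = PerturbationSpec(noise_sd_gy=0.1, seed=5)
        a = perturb_dose(pd2_dose, spec)
        b = perturb_dose(pd2_dose, spec)
        np.testing.assert_array_equal(a.dose, b.dose)


class TestDegradeCt:
    def test_zero_degradation(self, phantom):
        ct, _, _ = phantom
        out = degrade_ct(ct, 0.0, 0.0)
        np.testing.assert_array_equal(out.data, ct.data)
        assert out.modality == Modality.PSEUDO_CT

    def test_pure_bias_rmse(self, phantom):
        ct, _, _ = phantom
        out = degrade_ct(ct, 20.0, 0.0)
        np.testing.assert_allclose(out.data - ct.data, 20.0)

    def test_mri_input_rejected(self, phantom):
        _, mri, _ = phantom
        with pytest.raises(ValueError, match="CT-like"):
            degrade_ct(mri, 10.0, 10.0)
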