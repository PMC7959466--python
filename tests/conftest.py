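import numpy as np
import pytest

from sctdose.grids import DoseGrid, ImageVolume, Modality, StructureMask, StructureRole
from sctdose.synthetic import PhantomSpec, Prescription, make_head_phantom, make_srt_dose


@pytest.fixture(scope="session")
def phantom():
    """Default-size head phantom (CT, MRI, structures); shared, read-only."""
    return make_head_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Piecewise-constant phantom without CT/MRI noise for exact class checks."""
    return make_head_phantom(PhantomSpec(ct_noise_sd=0.0, mri_noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def pd2_dose(phantom):
    ct, _, structures = phantom
    return make_srt_dose(structures, Prescription.pd2(), ct)


def gaussian_blob_dose(seed: int, n: int = 16, spacing: float = 2.0) -> DoseGrid:
    """Smooth single-lobe dose field on a small grid (SRT-like falloff).

    The width keeps the 10% isodose strictly inside the grid, as for a
    clinical SRT dose fully contained in the scored volume.
    """
    rng = np.random.default_rng(seed)
    center = rng.uniform(0.44 * n * spacing, 0.56 * n * spacing, 3)
    width = rng.uniform(55.0, 80.0)
    ax = [np.arange(n) * spacing for _ in range(3)]
    z, y, x = np.meshgrid(*ax, indexing="ij")
    r2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    return DoseGrid(33.0 * np.exp(-r2 / width), (spacing,) * 3)


def box_mask(shape, spacing=(1.0, 1.0, 1.0), name="box", role=StructureRole.PTV):
    return StructureMask(name, role, np.ones(shape, dtype=bool), spacing)
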