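import numpy as np
import pytest

from earlyframe.mesh import Mesh, build_cohort_mesh, icosphere, triangle_grid
from earlyframe.synthetic import CohortConfig, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_mesh():
    """Two-hemisphere cohort mesh at desk scale (324 vertices)."""
    return build_cohort_mesh(subdivisions=2)


@pytest.fixture(scope="session")
def mesh3():
    """Finer cohort mesh used by recovery-style tests (1284 vertices)."""
    return build_cohort_mesh(subdivisions=3)


@pytest.fixture(scope="session")
def closed_mesh():
    """Single closed icosphere without patches (642 vertices)."""
    verts, faces = icosphere(3, 50.0)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return Mesh(verts, faces, normals, np.full(len(verts), 2.5), {})


@pytest.fixture(scope="session")
def flat_mesh():
    """Flat regular triangular lattice, 41 x 41, unit spacing."""
    return triangle_grid(41, 41, 1.0)


@pytest.fixture(scope="session")
def small_cohort(small_mesh):
    cfg = CohortConfig(n_yhc=2, n_ehc=8, n_amci=4, n_add=4, seed=7)
    return generate_cohort(cfg, small_mesh)


@pytest.fixture(scope="session")
def phantom6():
    return generate_phantom(psf_fwhm_mm=6.0)


def gm_core_mask(phantom):
    """Voxels in the radial middle of the GM shell, away from interfaces."""
    shape = phantom.activity.shape
    center = (np.array(shape) - 1) / 2.0 * phantom.voxel_mm
    idx = np.indices(shape).reshape(3, -1).T * phantom.voxel_mm
    r = np.linalg.norm(idx - center, axis=1).reshape(shape)
    return (r > 17.5) & (r < 20.5)
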