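import numpy as np
import pytest

from laminarkit.surface import SurfaceMesh
from laminarkit.synth import PhantomSpec, Septum, gen_cortex_phantom


def make_grid_mesh(nx: int, ny: int, pitch: float = 1.0, overlays=None) -> SurfaceMesh:
    """Planar triangulated grid in the z=0 plane."""
    gx, gy = np.meshgrid(
        np.arange(nx) * pitch, np.arange(ny) * pitch, indexing="ij"
    )
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    tris = []
    for ix in range(nx - 1):
        for iy in range(ny - 1):
            a = ix * ny + iy
            b = (ix + 1) * ny + iy
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(tris), overlays or {})


@pytest.fixture
def grid_mesh_5x5():
    return make_grid_mesh(5, 5)


@pytest.fixture(scope="session")
def septum_phantom():
    """Phantom with a single septum at the face/hand boundary (y = 12 mm)."""
    spec = PhantomSpec(cohort="younger", seed=11, septa=(Septum(y_mm=12.0),))
    return gen_cortex_phantom(spec), spec


@pytest.fixture(scope="session")
def null_phantom():
    spec = PhantomSpec(cohort="younger", seed=12)
    return gen_cortex_phantom(spec), spec


def phantom_seed_pair(phantom):
    """Inferior/superior seed vertices on the central column of a strip."""
    nx, ny = phantom.truth["grid_shape"]
    col = nx // 2
    return col * ny, col * ny + ny - 1
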