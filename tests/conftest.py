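import numpy as np
import pytest

from xrftopo.forward import BeamConfig
from xrftopo.geometry import default_detectors
from xrftopo.grid import VoxelGrid
from xrftopo.phantom import canonical_spec, build_phantom


@pytest.fixture(scope="session")
def truth_grid():
    return build_phantom(canonical_spec())


@pytest.fixture(scope="session")
def beam():
    return BeamConfig()


@pytest.fixture(scope="session")
def detectors():
    return default_detectors((40.0, 40.0))


def make_slab(ny=5, nx=5, t_vox=3, nz=6, voxel_size=1.0, density=1.25,
              fractions=None):
    """Uniform support-resting slab with LoVo-like composition."""
    fractions = fractions or {"C": 0.61, "N": 0.17, "O": 0.16, "H": 0.06}
    t = np.full((ny, nx), t_vox, dtype=np.int64)
    fr2d = {s: np.full((ny, nx), w) for s, w in fractions.items()}
    return VoxelGrid.from_columns(t, None, nz, voxel_size, density, fr2d)


@pytest.fixture
def slab():
    return make_slab()


def reference_line_integral(field, voxel_size, p0, p1):
    """Independent exact line-integral oracle: collect every axis-plane
    crossing of the segment, sort the parameters, and look up the cell
    at each sub-segment midpoint (no incremental walking)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    nz, ny, nx = field.shape
    ts = [0.0, 1.0]
    for axis, n in ((0, nx), (1, ny), (2, nz)):
        if d[axis] == 0:
            continue
        for i in range(n + 1):
            t = (i * voxel_size - p0[axis]) / d[axis]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(ts)
    total = 0.0
    seg = np.linalg.norm(d)
    for a, b in zip(ts[:-1], ts[1:]):
        mid = p0 + 0.5 * (a + b) * d
        ix, iy, iz = (int(mid[0] // voxel_size), int(mid[1] // voxel_size),
                      int(mid[2] // voxel_size))
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            total += field[iz, iy, ix] * (b - a) * seg
    return total
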