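import numpy as np
import pytest
import trimesh

import lvshape as lv


@pytest.fixture(scope="session")
def sphere10():
    """Fine icosphere of radius 10 mm (analytic test solid)."""
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


def sphere_mask(radius=15.0, n=40, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2.0
    r2 = sum(((idx[k] - c) * spacing[k]) ** 2 for k in range(3))
    return lv.VoxelMask(
        (r2 <= radius ** 2).astype(np.uint8), tuple(float(s) for s in spacing)
    )


@pytest.fixture(scope="session")
def sphere_mask15():
    return sphere_mask()


@pytest.fixture(scope="session")
def phantom_mesh_small():
    """One small phantom through the full mesh path at a reduced vertex
    budget (keeps unit tests quick; the 24,000 contract is tested
    separately)."""
    spec = lv.PhantomSpec(
        n_per_class=1, semi_axes=(12.0, 9.0, 15.0), grid_size=64, seed=7
    )
    mask, _ = lv.generate_phantom_cohort(spec)[0]
    cfg = lv.MeshConfig(target_vertices=6000)
    return lv.extract_mesh(mask, cfg)


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
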