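import numpy as np
import pytest
import trimesh

from hemoplan import (
    HematomaMask,
    HematomaSpec,
    PhantomSpec,
    SkullSpec,
    SurfaceMesh,
    make_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless 128-mm head phantom with an unrotated (30, 15, 10) mm lesion."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sd=5.0, seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """96-mm grid phantom used where many phantoms must be generated."""
    return PhantomSpec(
        grid_shape=(96, 96, 96),
        skull=SkullSpec(outer_semi_axes=(44.0, 42.0, 40.0), thickness_mm=5.0),
        hematoma=HematomaSpec(centroid_mm=(0.0, 0.0, 0.0), semi_axes_mm=(27.0, 13.0, 9.0)),
    )


@pytest.fixture(scope="session")
def sphere_mesh_r20():
    """Finely tessellated sphere of radius 20 mm (max radial error << 0.1 mm)."""
    m = trimesh.creation.icosphere(subdivisions=5, radius=20.0)
    return SurfaceMesh.from_trimesh(m)


def make_shell_mesh(outer_r=60.0, inner_r=54.0, subdivisions=4):
    """Spherical skull shell: two nested closed sphere surfaces in one mesh."""
    outer = trimesh.creation.icosphere(subdivisions=subdivisions, radius=outer_r)
    inner = trimesh.creation.icosphere(subdivisions=subdivisions, radius=inner_r)
    combined = trimesh.util.concatenate([outer, inner])
    return SurfaceMesh.from_trimesh(combined)


@pytest.fixture(scope="session")
def shell_mesh():
    return make_shell_mesh()


def ball_mask(radius_mm, grid=64, spacing=1.0, center=(0.0, 0.0, 0.0)):
    """Standalone voxelized ball mask (voxel-centre membership)."""
    origin = -(grid - 1) * spacing / 2.0
    ax = origin + np.arange(grid) * spacing
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    inside = (
        (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2 <= radius_mm**2
    )
    return HematomaMask(mask=inside, spacing=(spacing,) * 3, origin=(origin,) * 3)
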