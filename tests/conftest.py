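import numpy as np
import pytest

from asymsurf.mesh_core import surface_from_mesh
from asymsurf.octasphere import make_octasphere


@pytest.fixture(scope="session")
def mesh_lv2():
    return make_octasphere(2)


@pytest.fixture(scope="session")
def mesh_lv3():
    return make_octasphere(3)


@pytest.fixture(scope="session")
def mesh_lv4():
    return make_octasphere(4)


@pytest.fixture(scope="session")
def sphere_lv3(mesh_lv3):
    return surface_from_mesh(mesh_lv3)


@pytest.fixture(scope="session")
def sphere_lv4(mesh_lv4):
    return surface_from_mesh(mesh_lv4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def rotation_matrix(axis, angle):
    """Rodrigues rotation, used as an analytic oracle in several suites."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def band_limited_field(mesh, seed, band=(3, 8)):
    from asymsurf.synth_cohort import generate_template_pattern

    return generate_template_pattern(mesh, seed, band=band).values


def smooth_random_warp(mesh, seed, mean_disp_rad, band=(1, 2)):
    from asymsurf.synth_cohort import random_smooth_warp

    return random_smooth_warp(
        mesh, np.random.default_rng(seed), mean_disp_rad, band=band
    )
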