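import numpy as np
import pytest

from carposeg import PhantomSpec, cortical_seed, generate_phantom


@pytest.fixture(scope="session")
def sphere_spec():
    """Noiseless 6 mm sphere at the study voxel spacing."""
    return PhantomSpec(semi_axes=(6.0, 6.0, 6.0), shell_thickness_mm=1.2, noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def sphere_phantom(sphere_spec):
    volume, truth = generate_phantom(sphere_spec)
    return sphere_spec, volume, truth


@pytest.fixture(scope="session")
def thin_shell_spec():
    """6 mm sphere with a 0.8 mm cortical shell (thin relative to the
    1.0 mm smoothing kernel), noisy as in a real acquisition."""
    return PhantomSpec(semi_axes=(6.0, 6.0, 6.0), shell_thickness_mm=0.8, noise_sd_hu=20.0, seed=7)


@pytest.fixture(scope="session")
def thin_shell_phantom(thin_shell_spec):
    volume, truth = generate_phantom(thin_shell_spec)
    return thin_shell_spec, volume, truth


@pytest.fixture(scope="session")
def small_sphere_spec():
    """4 mm sphere: fits a 64^3 grid; used for fast and oracle tests."""
    return PhantomSpec(
        semi_axes=(4.0, 4.0, 4.0), shell_thickness_mm=1.0, noise_sd_hu=20.0,
        margin_voxels=7, seed=0,
    )


@pytest.fixture(scope="session")
def seed_of():
    return cortical_seed
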