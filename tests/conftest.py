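import numpy as np
import pytest

from scpsizer import (
    AcquisitionSpec,
    MediumConditions,
    PopulationMode,
    diffusion_coefficient_sphere,
)


@pytest.fixture(scope="session")
def water():
    """Water at 25 degC, the default medium."""
    return MediumConditions()


@pytest.fixture(scope="session")
def d_100nm(water):
    """Stokes-Einstein diffusion coefficient of a 100 nm sphere in water."""
    return diffusion_coefficient_sphere(100e-9, water)


@pytest.fixture()
def sphere_100nm_mode():
    """Monodisperse 100 nm spheres at a density giving ~300 particles in 15 pL."""
    return PopulationMode(shape="sphere", rh=100e-9, number_density=300 / 1.5e-8)


def make_brownian_track(D, n_steps, dt, rng, noise_sd=0.0, track_id=0):
    """Free 2-D Brownian track with per-axis step variance 2 D dt."""
    from scpsizer import Track

    steps = rng.standard_normal((n_steps, 2)) * np.sqrt(2.0 * D * dt)
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if noise_sd > 0:
        pos = pos + rng.standard_normal(pos.shape) * noise_sd
    return Track(track_id=track_id, frames=np.arange(n_steps + 1), positions=pos)
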