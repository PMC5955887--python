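import numpy as np
import pytest

import dimerkin as dk
from dimerkin.geometry import synthetic_protomer_template


@pytest.fixture(scope="session")
def template():
    return synthetic_protomer_template()


@pytest.fixture(scope="session")
def free_world():
    return dk.SyntheticWorld(seed=11)


@pytest.fixture(scope="session")
def free_trajs(free_world):
    """16 free-diffusion trajectories, 360 μs each at 0.01 μs resolution.

    The relative-position mixing time in the 15 nm box is ~0.6 μs, so this
    gives ~10⁴ effectively independent configurations for distribution tests.
    """
    return dk.simulate_unbiased(free_world, 16, 360_000, dt=1e-3, stride=10)


@pytest.fixture(scope="session")
def well_world():
    well = dk.Well(alpha1_center=0.0, alpha2_center=0.0, d_center=3.0,
                   depth=2.5, width_d=0.4, width_alpha=0.5)
    return dk.SyntheticWorld(wells=(well,), seed=13)


@pytest.fixture(scope="session")
def well_trajs(well_world):
    """Eight single-well trajectories, 30 μs each."""
    return dk.simulate_unbiased(well_world, 8, 300_000, dt=1e-4, stride=20)


@pytest.fixture(scope="session")
def discrete_truth():
    return dk.generate_discrete_truth(12, 3, seed=5, n_blocks=3, coupling=0.02)
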