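import numpy as np
import pytest

from coswater.forcefield import default_forcefield
from coswater.synthetic import NoiseSpec, SoluteSpec, generate_dataset

# small, fast synthetic settings shared by the unit tests; the acceptance
# tests use the full-size study conditions instead
FAST_SHELL_KW = dict(number_density=8.0, shell_outer=0.9)


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def solute(ff):
    return SoluteSpec.from_forcefield(ff)


@pytest.fixture(scope="session")
def aniso_solute(ff):
    return SoluteSpec.from_forcefield(ff, alpha_diag=[1.2e-3, 0.9e-3, 1.0e-3])


@pytest.fixture(scope="session")
def noiseless_dataset(aniso_solute):
    """25 noise-free frames with an anisotropic ground truth."""
    return generate_dataset(25, aniso_solute, seed=101, **FAST_SHELL_KW)


@pytest.fixture(scope="session")
def noisy_dataset(solute):
    """60 frames with grid noise and per-frame inhomogeneity."""
    return generate_dataset(
        60,
        solute,
        seed=202,
        noise=NoiseSpec(inhomogeneity=0.3),
        relative_grid_noise=0.05,
        **FAST_SHELL_KW,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
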