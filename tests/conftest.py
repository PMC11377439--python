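import numpy as np
import pytest

from vortexmc import BeamSpec, MediumOptics, PixelGrid

HENE = 633e-6  # mm


@pytest.fixture(scope="session")
def lg5():
    return BeamSpec(5, 0, 0.8, HENE)


@pytest.fixture(scope="session")
def lg3():
    return BeamSpec(3, 0, 0.8, HENE)


@pytest.fixture(scope="session")
def gauss():
    return BeamSpec(0, 0, 0.8, HENE)


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)


@pytest.fixture(scope="session")
def slab_mus4():
    """1 mm tissue-like slab with moderate scattering."""
    return MediumOptics(mus=4.0, mua=0.01, g=0.8, n=1.4, thickness=1.0)


@pytest.fixture(scope="session")
def clear_slab():
    """Index-matched, non-scattering 1 mm slab (ballistic propagation)."""
    return MediumOptics(mus=0.0, mua=0.0, g=0.8, n=1.0, thickness=1.0)


@pytest.fixture(scope="session")
def grid128():
    return PixelGrid.centered(128, 0.04)
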