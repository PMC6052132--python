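import numpy as np
import pytest

from musclesim import (
    ActivationParams,
    ConstitutiveParams,
    FiberConductionParams,
    HodgkinHuxleyFixture,
    StimulusProtocol,
    build_cube_geometry,
)


@pytest.fixture(scope="session")
def cell_model():
    """Shared excitable fixture model (resting state cached)."""
    return HodgkinHuxleyFixture()


@pytest.fixture(scope="session")
def act_params():
    return ActivationParams()


@pytest.fixture(scope="session")
def conduction():
    return FiberConductionParams()


@pytest.fixture(scope="session")
def twitch_protocol():
    return StimulusProtocol(amplitude=1200.0, t_start=0.0, t_end=0.1)


@pytest.fixture
def unit_geom():
    """Minimal 1-element geometry with one single-element fiber."""
    return build_cube_geometry(
        elements3d=(1, 1, 1),
        fibers_per_cross_section_element=(1, 1),
        elements_per_fiber_per_3d_element=1,
    )


@pytest.fixture
def small_geom():
    """2×2×2-element cube with 4×4 fibers, 3 fiber elements per 3D element."""
    return build_cube_geometry(
        elements3d=(2, 2, 2),
        fibers_per_cross_section_element=(2, 2),
        elements_per_fiber_per_3d_element=3,
    )


@pytest.fixture
def single_fiber_geom():
    """One 3D element holding a single 50-element fiber along x."""
    return build_cube_geometry(
        elements3d=(1, 1, 1),
        fibers_per_cross_section_element=(1, 1),
        elements_per_fiber_per_3d_element=50,
    )


@pytest.fixture(scope="session")
def mech_params():
    return ConstitutiveParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
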