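import numpy as np
import pytest

from fusesim.construct import ConstructParams, build_construct


@pytest.fixture(scope="session")
def small_params():
    """A reduced construct for fast unit tests (same topology as default)."""
    return ConstructParams(
        vertebra_width=24.0,
        vertebra_depth=20.0,
        vertebra_height=10.0,
        disc_space_height=6.0,
        cage_height=6.0,
        cage_width=6.0,
        cage_depth=12.0,
        cage_lateral_offset=5.0,
        fixation_rod_section=9.0,
        fixation_lateral_offset=8.5,
        inplane_edge=2.5,
        callus_axial_edge=2.0,
        vertebra_axial_edge=3.0,
    )


@pytest.fixture(scope="session")
def small_mesh(small_params):
    return build_construct(small_params)


@pytest.fixture(scope="session")
def default_mesh():
    return build_construct()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
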