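import numpy as np
import pytest

import mapcrystal as mc


@pytest.fixture(scope="session")
def small_grid():
    return mc.GridSpec(32, 32, 4, 4)


@pytest.fixture(scope="session")
def grid64():
    return mc.GridSpec(64, 64, 8, 8)


@pytest.fixture(scope="session")
def coupled_state(small_grid):
    """Random smooth two-field state for force/energy consistency tests."""
    z = mc.bandpass_gwn(small_grid, target_power=0.03, seed=1)
    o = mc.bandpass_gwn(small_grid, target_power=0.2, seed=2,
                        complex_valued=False)
    return mc.FieldState(0.0, z, (o,))


@pytest.fixture(scope="session")
def uncoupled_model(small_grid):
    return mc.ModelSpec(r_z=0.05,
                        fields=(mc.RealFieldSpec(r=0.25, gamma=0.2),),
                        grid=small_grid)
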