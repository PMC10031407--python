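import numpy as np
import pytest

from wingsense.wing_model import Kinematics, WingSpec, simulate_strain


@pytest.fixture(scope="session")
def tiny_spec():
    return WingSpec(gradient="gradient", zeta=2.0)


@pytest.fixture(scope="session")
def tiny_flap(tiny_spec):
    """Coarse-mesh flap-only simulation for fast pipeline tests."""
    return simulate_strain(tiny_spec, Kinematics(rotation_axis="none"),
                           nx=10, ny=5, n_cycles=4)


@pytest.fixture(scope="session")
def tiny_yaw(tiny_spec):
    return simulate_strain(tiny_spec, Kinematics(rotation_axis="yaw"),
                           nx=10, ny=5, n_cycles=4)


@pytest.fixture(scope="session")
def grid_pair():
    """Full-grid gradient wing, flap-only and yaw conditions (shared)."""
    spec = WingSpec(gradient="gradient", E_mean=3e9, zeta=2.0)
    flap = simulate_strain(spec, Kinematics(rotation_axis="none"))
    rot = simulate_strain(spec, Kinematics(rotation_axis="yaw"),
                          n_cycles=flap.provenance["cycles_run"])
    return spec, flap, rot


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
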