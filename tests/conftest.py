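import numpy as np
import pytest

from swirsr.constants import ProbeGeometry, default_water_table


@pytest.fixture(scope="session")
def geometry():
    """Default probe geometry (tunnel-derived acceptance cone)."""
    return ProbeGeometry()


@pytest.fixture(scope="session")
def open_geometry():
    """Probe geometry with a wide-open acceptance cone (desk-scale MC)."""
    return ProbeGeometry(acceptance_half_angle_deg=90)


@pytest.fixture(scope="session")
def water_table():
    return default_water_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


#: (group il%, per-wavelength mu_s' regime) used in closed-loop scenarios;
#: values sit in the middle of the recovered ranges of the two phantom groups.
GROUP_MUSP = {
    10: {1450: 2.05, 1650: 1.65},
    20: {1450: 4.20, 1650: 3.10},
}


@pytest.fixture(scope="session")
def group_musp():
    return GROUP_MUSP
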