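import numpy as np
import pytest

from flospec import EnergyLandscape, Environment, LoadingRate, TetherGeometry


@pytest.fixture(scope="session")
def env() -> Environment:
    """Room-temperature aqueous environment, k_BT = 4.114 pN·nm."""
    return Environment.from_thermal_energy(4.114)


@pytest.fixture(scope="session")
def dig_landscape() -> EnergyLandscape:
    """DIG/anti-DIG antibody bond parameters."""
    return EnergyLandscape(k_off=4.0e-4, delta_x=0.76)


@pytest.fixture(scope="session")
def rate_05() -> LoadingRate:
    return LoadingRate(f_dot=0.5)


@pytest.fixture(scope="session")
def standard_tether() -> TetherGeometry:
    """2.2 µm bead on a ~1.9 µm dsDNA tether."""
    return TetherGeometry(bead_radius=1100.0, tether_extension=1900.0)
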