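import numpy as np
import pytest

from xspol import bem
from xspol.cavity import Cavity, build_cavity, tessellate
from xspol.fixtures import load_tables
from xspol.geometry import water_geometry

EPS_WATER = 1.7485


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def sphere_l3():
    """Radius-2 sphere cavity + assembled BEM system at water optical ε."""
    return bem.sphere_system(2.0, EPS_WATER, level=3)


@pytest.fixture(scope="session")
def sphere_l2():
    return bem.sphere_system(2.0, EPS_WATER, level=2)


@pytest.fixture(scope="session")
def water_cavity():
    return build_cavity(water_geometry())


@pytest.fixture()
def unit_sphere_cavity():
    return Cavity(centers=np.zeros((1, 3)), radii=np.array([1.0]))
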