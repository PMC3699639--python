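import math

import numpy as np
import pytest

from sepcm import Molecule, load_parameters
from sepcm.units import ANGSTROM_TO_BOHR


@pytest.fixture(scope="session")
def pm3():
    return load_parameters("PM3")


@pytest.fixture(scope="session")
def am1():
    return load_parameters("AM1")


@pytest.fixture(scope="session")
def mndo():
    return load_parameters("MNDO")


def molecule(symbols, coords_angstrom, charge=0):
    return Molecule(tuple(symbols), np.asarray(coords_angstrom, float) * ANGSTROM_TO_BOHR, charge)


@pytest.fixture
def h2():
    return molecule(["H", "H"], [[0, 0, 0], [0, 0, 0.699]])


@pytest.fixture
def h2o():
    return molecule(["O", "H", "H"], [[0, 0, 0.06], [0, 0.76, -0.47], [0, -0.76, -0.47]])


@pytest.fixture
def nh3():
    return molecule(
        ["N", "H", "H", "H"],
        [[0, 0, 0.1], [0.94, 0, -0.27], [-0.47, 0.81, -0.27], [-0.47, -0.81, -0.27]],
    )


@pytest.fixture
def ch4():
    a = 1.09 / math.sqrt(3)
    return molecule(
        ["C", "H", "H", "H", "H"],
        [[0, 0, 0], [a, a, a], [-a, -a, a], [-a, a, -a], [a, -a, -a]],
    )


@pytest.fixture
def nh4_cation():
    a = 1.02 / math.sqrt(3)
    return molecule(
        ["N", "H", "H", "H", "H"],
        [[0.02, 0.01, 0], [a, a, a], [-a, -a, a], [-a, a, -a], [a, -a, -a]],
        charge=1,
    )


def random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
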