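import math

import numpy as np
import pytest

from semicell.lattice import Cell, build_crystal_fixture
from semicell.scf import SCFOptions, scf_run

# published equilibrium geometries of the reference molecules (Å, degrees)
AM1_WATER = (0.961, 103.5)
MNDO_WATER = (0.943, 106.8)
AM1_METHANE = 1.112
MNDO_METHANE = 1.104


def water_cell(r, theta_deg):
    t = math.radians(theta_deg)
    return Cell(("O", "H", "H"),
                np.array([[0.0, 0.0, 0.0],
                          [r, 0.0, 0.0],
                          [r * math.cos(t), r * math.sin(t), 0.0]]))


def methane_cell(r):
    d = r / math.sqrt(3.0)
    return Cell(("C", "H", "H", "H", "H"),
                np.array([[0.0, 0.0, 0.0], [d, d, d], [d, -d, -d],
                          [-d, d, -d], [-d, -d, d]]))


def h2_cell(r=0.677):
    return Cell(("H", "H"), np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


@pytest.fixture(scope="session")
def am1_water():
    cell = water_cell(*AM1_WATER)
    return cell, scf_run(cell, "AM1")


@pytest.fixture(scope="session")
def am1_methane():
    cell = methane_cell(AM1_METHANE)
    return cell, scf_run(cell, "AM1")


@pytest.fixture(scope="session")
def diamond_cell():
    return build_crystal_fixture("diamond")


@pytest.fixture(scope="session")
def am1_diamond(diamond_cell):
    return scf_run(diamond_cell, "AM1")


@pytest.fixture(scope="session")
def tight_options():
    return SCFOptions(tol_energy=1e-8, tol_density=1e-8, max_iter=400)
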