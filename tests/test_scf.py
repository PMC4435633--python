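import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semicell.lattice import Cell, build_crystal_fixture
from semicell.parameters import get_element_params
from semicell.scf import (SCFOptions, build_core_hamiltonian, compensated_sum,
                          coulson_charges, dipole_moment, heat_of_formation,
                          scf_run)

from conftest import h2_cell, methane_cell, water_cell, AM1_WATER


# -- compensated summation --------------------------------------------------

def test_compensated_sum_cancellation_cases():
    assert compensated_sum([1e16, 1.0, -1e16]) == 1.0
    assert compensated_sum([]) == 0.0
    assert compensated_sum(10 ** 6 * [0.1]) == pytest.approx(1e5, rel=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=-1e12, max_value=1e12,
                          allow_nan=False), min_size=0, max_size=200))
def test_compensated_sum_matches_fsum(values):
    """math.fsum is exact in double precision: the extended-precision oracle."""
    expected = math.fsum(values)
    got = compensated_sum(values)
    assert got == pytest.approx(expected, rel=1e-15, abs=1e-300)


def test_compensated_sum_adversarial_alternating():
    rng = np.random.default_rng(9)
    big = rng.uniform(1e14, 1e16, size=500)
    small = rng.uniform(-1.0, 1.0, size=500)
    seq = np.concatenate([big, small, -big])
    assert compensated_sum(seq) == pytest.approx(math.fsum(seq), rel=1e-13)


# -- core Hamiltonian -------------------------------------------------------

def test_isolated_hydrogen_core_is_uss():
    h = Cell(("H",), np.zeros((1, 3)))
    hc = build_core_hamiltonian(h, "AM1")
    assert hc.shape == (1, 1)
    assert hc[0, 0] == pytest.approx(get_element_params("H", "AM1").uss)


def test_core_hamiltonian_hermitian(am1_water):
    cell, _ = am1_water
    hc = build_core_hamiltonian(cell, "AM1")
    assert np.max(np.abs(hc - hc.T)) < 1e-10
    per = build_core_hamiltonian(build_crystal_fixture("wurtzite"), "AM1")
    assert np.max(np.abs(per - per.T)) < 1e-10


def test_overlapping_atoms_rejected():
    bad = Cell(("H", "H"), np.array([[0.0, 0, 0], [0.05, 0, 0]]))
    with pytest.raises(ValueError, match="overlap"):
        build_core_hamiltonian(bad, "AM1")


# -- gas-phase oracles ------------------------------------------------------

def test_isolated_zinc_atom_identities():
    """A one-atom cell reproduces its tabulated atomic quantities exactly."""
    zn = Cell(("Zn",), np.zeros((1, 3)))
    st_ = scf_run(zn, "AM1")
    p = get_element_params("Zn", "AM1")
    assert st_.converged and len(st_.history) <= 10
    assert st_.e_total == pytest.approx(p.eisol, abs=1e-8)
    assert st_.heat_formation == pytest.approx(p.eheat, abs=1e-8)
    assert coulson_charges(st_, zn)[0] == pytest.approx(0.0, abs=1e-12)


def test_hydrogen_molecule_published_values():
    """MNDO/AM1 H2 heats of formation at the published bond lengths."""
    st_m = scf_run(h2_cell(0.663), "MNDO")
    st_a = scf_run(h2_cell(0.677), "AM1")
    assert st_m.heat_formation == pytest.approx(0.7, abs=0.1)
    assert st_a.heat_formation == pytest.approx(-5.2, abs=0.1)
    # homonuclear symmetry
    q = coulson_charges(st_a, h2_cell(0.677))
    assert np.allclose(q, 0.0, atol=1e-10)


def test_water_am1_dipole_and_charge_structure(am1_water):
    cell, st_ = am1_water
    q = coulson_charges(st_, cell)
    assert q[0] < 0 < q[1]
    assert q.sum() == pytest.approx(0.0, abs=1e-8)
    mu = np.linalg.norm(dipole_moment(st_, cell))
    assert mu == pytest.approx(1.86, abs=0.03)


def test_scf_energy_orbital_consistency(am1_water):
    """Tr(P F) equals twice the sum of occupied orbital energies."""
    cell, st_ = am1_water
    from semicell.scf import _System
    f = _System(cell, "AM1", SCFOptions()).build_fock(st_.density)
    tr = float(np.vdot(st_.density, f))
    assert tr == pytest.approx(
        2.0 * st_.orbital_energies[: st_.n_occupied].sum(), abs=1e-3)


def test_density_trace_and_idempotency(am1_water):
    _, st_ = am1_water
    p = st_.density
    assert np.trace(p) == pytest.approx(st_.n_electrons, abs=1e-8)
    assert np.max(np.abs(p @ p / 2.0 - p)) < 1e-6
    assert np.all(np.diff(st_.orbital_energies) >= -1e-10)


def test_scf_runs_are_deterministic():
    cell = water_cell(*AM1_WATER)
    a = scf_run(cell, "AM1")
    b = scf_run(cell, "AM1")
    assert a.e_total == b.e_total
    assert np.array_equal(a.density, b.density)


def test_molecular_translation_invariance():
    cell = water_cell(*AM1_WATER)
    shifted = Cell(cell.symbols, cell.positions + [3.7, -1.2, 9.9])
    e0 = scf_run(cell, "AM1").e_total
    e1 = scf_run(shifted, "AM1").e_total
    assert abs(e0 - e1) < 1e-8


# -- error handling ---------------------------------------------------------

def test_open_shell_rejected():
    na = Cell(("Na",), np.zeros((1, 3)))
    with pytest.raises(ValueError, match="open shell"):
        scf_run(na, "AM1")


def test_charged_periodic_rejected():
    cell = build_crystal_fixture("diamond").with_charge(2)
    with pytest.raises(ValueError, match="neutral"):
        scf_run(cell, "AM1")


def test_charged_molecule_allowed():
    # hydronium: 8 valence electrons, closed shell
    h3o = Cell(("O", "H", "H", "H"),
               np.array([[0.0, 0, 0], [0.98, 0, 0],
                         [-0.49, 0.85, 0], [-0.49, -0.85, 0]]),
               charge=1)
    st_ = scf_run(h3o, "AM1")
    assert st_.converged
    assert st_.n_electrons == 8
    assert coulson_charges(st_, h3o).sum() == pytest.approx(1.0, abs=1e-8)


def test_unconverged_state_refuses_heat():
    cell = water_cell(*AM1_WATER)
    st_ = scf_run(cell, "AM1", SCFOptions(max_iter=2))
    assert not st_.converged
    with pytest.raises(ValueError, match="unconverged"):
        heat_of_formation(st_, cell)


def test_invalid_options_rejected():
    with pytest.raises(ValueError, match="damping onset"):
        SCFOptions(screening_r=8.0)     # alpha = 7.6 bohr < c_cut


# -- periodic behaviour -----------------------------------------------------

def test_molecular_crystal_extensivity():
    """Cells whose images are fully decoupled (all beyond 2α) are exactly
    extensive: n-fold replication multiplies ΔH_f by n."""
    base = build_crystal_fixture("molecular_box", box=35.0)
    opts = SCFOptions(screening_r=30.0)
    st1 = scf_run(base, "AM1", opts)
    big = build_crystal_fixture("molecular_box", (2, 1, 1), box=35.0)
    st2 = scf_run(big, "AM1", opts)
    assert st2.heat_formation == pytest.approx(2 * st1.heat_formation,
                                               rel=1e-6)
    # and each equals the free molecule
    gas = scf_run(Cell(base.symbols, base.positions), "AM1")
    assert st1.heat_formation == pytest.approx(gas.heat_formation, rel=1e-9)


def test_periodic_fock_reduces_to_gas_phase_in_huge_box():
    box = build_crystal_fixture("molecular_box", box=70.0)
    gas = Cell(box.symbols, box.positions)
    from semicell.scf import _System
    opts = SCFOptions()
    sys_p = _System(box, "AM1", opts)
    sys_g = _System(gas, "AM1", opts)
    p = scf_run(gas, "AM1").density
    # H_core alone carries the constant image potentials; they cancel
    # exactly against the electron-electron and core-core constants, so the
    # Fock matrix (and every observable) reduces to the gas phase
    assert np.max(np.abs(sys_p.build_fock(p) - sys_g.build_fock(p))) < 1e-10
    dh = sys_p.h_core - sys_g.h_core
    assert np.max(np.abs(dh - np.diag(np.diag(dh)))) < 1e-10


def test_wurtzite_charge_transfer_direction():
    cell = build_crystal_fixture("wurtzite")
    st_ = scf_run(cell, "AM1")
    q = coulson_charges(st_, cell)
    assert st_.converged
    assert q[0] > 0.2 and q[2] < -0.2          # Zn positive, O negative
    assert q.sum() == pytest.approx(0.0, abs=1e-8)
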