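import itertools
import math

import numpy as np
import pytest

from semicell import integrals as I
from semicell.constants import EV_PER_HARTREE
from semicell.parameters import SUPPORTED_ELEMENTS, get_element_params


def rotation(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# -- Klopman kernel ---------------------------------------------------------

def test_klopman_pair_term_cases():
    assert I.klopman_pair_term(1, 1, 0.0, 0.5, 0.5) == pytest.approx(1.0)
    r = 1e4
    # additive-radius deviation from bare Coulomb is (rho_a+rho_b)^2/(2r^2)
    assert I.klopman_pair_term(1, 1, r, 0.5, 0.5) == pytest.approx(
        1.0 / r, rel=1e-8)
    rng = np.random.default_rng(1)
    for _ in range(50):
        q1, q2 = rng.normal(size=2)
        r, ra, rb = rng.uniform(0.1, 10, size=3)
        direct = q1 * q2 / math.sqrt(r * r + (ra + rb) ** 2)
        assert I.klopman_pair_term(q1, q2, r, ra, rb) == pytest.approx(direct)
        assert I.klopman_pair_term(q1, q2, r, ra, rb) == pytest.approx(
            I.klopman_pair_term(q2, q1, r, rb, ra))


# -- damped gamma -----------------------------------------------------------

def test_gamma_monotone_and_bare_coulomb_limit():
    h = get_element_params("H", "AM1")
    r = np.linspace(0.5, 120, 4000)
    g = I.gamma_damped(r, h.g_monopole, h.g_monopole, 10.0)
    assert np.all(np.diff(g) < 0)
    assert abs(100.0 * I.gamma_damped(100.0, h.g_monopole, h.g_monopole,
                                      10.0) - 1.0) < 1e-12


@pytest.mark.parametrize("ea", SUPPORTED_ELEMENTS)
def test_gamma_continuity_contract_all_pairs(ea):
    """|γ(c⁻) − γ(c⁺)| stays within the stated 5e-3 hartree for every
    supported element pair (exactly continuous under the adopted tail)."""
    pa = get_element_params(ea, "AM1")
    for eb in SUPPORTED_ELEMENTS:
        pb = get_element_params(eb, "AM1")
        lo = I.gamma_damped(10.0 - 1e-9, pa.g_monopole, pb.g_monopole, 10.0)
        hi = I.gamma_damped(10.0 + 1e-9, pa.g_monopole, pb.g_monopole, 10.0)
        assert abs(lo - hi) < 5e-3


def test_gamma_matches_klopman_below_cutoff():
    c = get_element_params("C", "AM1")
    o = get_element_params("O", "AM1")
    r = 4.0
    expected = I.klopman_pair_term(1, 1, r, c.rho0, o.rho0)
    assert I.gamma_damped(r, c.g_monopole, o.g_monopole, 10.0) \
        == pytest.approx(expected, rel=1e-14)


def test_gamma_alternative_tail_conventions():
    # literal additive parse of the published tail: 1/(r + (1/GA+1/GB)^2)
    # evaluated at the onset with G_A = G_B = 1 gives 1/14
    assert I.gamma_damped(10.0 + 1e-12, 1.0, 1.0, 10.0,
                          convention="eq_additive") \
        == pytest.approx(1.0 / 14.0, rel=1e-6)
    for conv in I.GAMMA_TAIL_CONVENTIONS:
        val = I.gamma_damped(40.0, 1.0, 1.0, 10.0, convention=conv)
        assert val == pytest.approx(1.0 / 40.0, rel=1e-6)
    with pytest.raises(ValueError, match="convention"):
        I.gamma_damped(5.0, 1.0, 1.0, 10.0, convention="bogus")
    with pytest.raises(ValueError):
        I.gamma_damped(-1.0, 1.0, 1.0, 10.0)


def test_neutral_atom_potential_decays_faster_than_r2():
    """Core and valence monopoles share the damped kernel, so a neutral
    atom's net potential vanishes identically; against a bare 1/r core the
    residual still dies off faster than 1/r^2 beyond the cutoff."""
    c = get_element_params("C", "AM1")
    r = np.array([12.0, 14.0, 16.0, 20.0, 30.0])
    g = I.gamma_damped(r, c.g_monopole, c.g_monopole, 10.0)
    resid = np.abs(r ** 2 * (g - 1.0 / r))
    assert np.all(np.diff(resid) <= 0)         # faster than 1/r^2
    assert np.all(resid[r >= 20.0] < 1e-12)    # Gaussian kills the tail
    # identical kernels for core and valence monopoles: exact cancellation
    assert np.all(np.abs(c.z_valence * g - c.z_valence * g) == 0.0)


# -- multipole charge sets --------------------------------------------------

def test_charge_set_structure():
    c = get_element_params("C", "AM1")
    mono, = I.multipole_charge_sets(c, (0, 0))
    assert mono.order == 0 and mono.charges == ((1.0, (0.0, 0.0, 0.0)),)
    dip, = I.multipole_charge_sets(c, (0, 3))
    assert dip.order == 1
    assert dip.total_charge == pytest.approx(0.0)
    assert {abs(p[2]) for _, p in dip.charges} == {c.d1}
    sets = I.multipole_charge_sets(c, (3, 3))
    assert [s.order for s in sets] == [0, 2]
    quad = sets[1]
    assert quad.total_charge == pytest.approx(0.0)
    sq, = I.multipole_charge_sets(c, (1, 2))
    dipole = np.sum([np.asarray(p) * q for q, p in sq.charges], axis=0)
    assert np.allclose(dipole, 0.0)


def test_charge_set_invariant_violations_rejected():
    with pytest.raises(ValueError, match="sum to zero"):
        I.MultipoleChargeSet(1, ((0.5, (0, 0, 1.0)),), 1.0)
    with pytest.raises(ValueError, match="dipole"):
        I.MultipoleChargeSet(2, ((0.5, (0, 0, 1.0)), (-0.5, (0, 0, 0.5))),
                             1.0)


# -- two-electron blocks ----------------------------------------------------

def test_ss_block_equals_gamma():
    h = get_element_params("H", "AM1")
    for r in (2.0, 9.0, 15.0):
        blk = I.eri_block(h, h, [0.0, 0.0, r], c_cut=10.0)
        gam = I.gamma_damped(r, h.g_monopole, h.g_monopole, 10.0)
        assert blk[0, 0, 0, 0] == pytest.approx(gam * EV_PER_HARTREE,
                                                rel=1e-12)


def test_one_center_limits():
    c = get_element_params("C", "AM1")
    blk = I.eri_block(c, c, [0.0, 0.0, 1e-7])
    assert blk[0, 0, 0, 0] == pytest.approx(c.gss, abs=1e-6)
    assert blk[0, 3, 0, 3] == pytest.approx(c.hsp, abs=1e-6)


def test_rotational_invariance_of_blocks():
    c = get_element_params("C", "AM1")
    o = get_element_params("O", "AM1")
    rng = np.random.default_rng(11)
    v = np.array([1.3, -0.4, 2.0])
    base = I.eri_block(c, o, v)
    for _ in range(5):
        q = rotation(rng)
        rot = I.eri_block(c, o, v @ q.T)
        w = np.zeros((4, 4))
        w[0, 0] = 1.0
        w[1:, 1:] = q
        ref = np.einsum("ai,bj,ck,dl,ijkl->abcd", w, w, w, w, base)
        assert np.max(np.abs(ref - rot)) < 1e-10


def test_block_symmetry_under_atom_exchange():
    c = get_element_params("C", "AM1")
    o = get_element_params("O", "AM1")
    v = np.array([0.8, 1.9, -1.1])
    ab = I.eri_block(c, o, v)
    ba = I.eri_block(o, c, -v)
    assert np.max(np.abs(ab - ba.transpose(2, 3, 0, 1))) < 1e-12
    # index symmetry within each center pair
    assert np.max(np.abs(ab - ab.transpose(1, 0, 2, 3))) < 1e-14
    assert np.max(np.abs(ab - ab.transpose(0, 1, 3, 2))) < 1e-14


def test_monopole_channels_positive():
    c = get_element_params("C", "AM1")
    h = get_element_params("H", "AM1")
    for r in (1.5, 3.0, 8.0, 20.0):
        blk = I.eri_block(c, h, [0.0, 0.0, r], c_cut=10.0)
        for mu in range(4):
            assert blk[mu, mu, 0, 0] > 0.0


def test_dipole_dipole_asymptote():
    """(s pz|s pz) along z approaches the point-dipole energy -2 μ1 μ2/R³."""
    c = get_element_params("C", "AM1")
    r = 80.0
    blk = I.eri_block(c, c, [0.0, 0.0, r])
    expected = -2.0 * c.d1 * c.d1 / r ** 3 * EV_PER_HARTREE
    assert blk[0, 3, 0, 3] == pytest.approx(expected, rel=2e-3)


def test_screened_block_collapses_to_monopoles():
    c = get_element_params("C", "AM1")
    alpha = 28.35  # bohr
    blk = I.eri_block(c, c, [0.0, 0.0, 2.2 * alpha], alpha=alpha, c_cut=10.0)
    gam = EV_PER_HARTREE / (1.5 * alpha)
    for i in range(4):
        for j in range(4):
            assert blk[i, i, j, j] == pytest.approx(gam, rel=1e-12)
    assert abs(blk[0, 3, 0, 3]) < 1e-12
    assert abs(blk[0, 3, 0, 0]) < 1e-12


# -- overlap / resonance ----------------------------------------------------

def test_1s1s_overlap_closed_form():
    rho = 1.4
    exact = math.exp(-rho) * (1 + rho + rho ** 2 / 3)
    val = I.sto_overlap_local(1, 0, 1.0, 1, 0, 1.0, np.array([1.4]))[0]
    assert val == pytest.approx(exact, abs=1e-12)


@pytest.mark.parametrize("na,la,za,nb,lb,zb,m", [
    (2, 0, 1.8, 1, 0, 1.2, 0),
    (2, 1, 1.7, 1, 0, 1.2, 0),
    (2, 1, 1.7, 2, 1, 2.3, 0),
    (2, 1, 1.7, 2, 1, 2.3, 1),
    (3, 0, 2.1, 2, 1, 1.6, 0),
])
def test_overlap_against_3d_quadrature(na, la, za, nb, lb, zb, m):
    """Independent oracle: direct Cartesian quadrature of the STO product."""
    r = 2.3
    val = I.sto_overlap_local(na, la, za, nb, lb, zb, np.array([r]), m=m)[0]

    n = 110
    lim = 14.0
    x = np.linspace(-lim, lim, n)
    dx = x[1] - x[0]
    xs, ys, zs = np.meshgrid(x, x, x + r / 2, indexing="ij", sparse=True)

    def sto(n_, l_, zeta, xx, yy, zz, axis):
        rr = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2) + 1e-30
        norm = (2 * zeta) ** (n_ + 0.5) / math.sqrt(math.factorial(2 * n_))
        rad = norm * rr ** (n_ - 1) * np.exp(-zeta * rr)
        if l_ == 0:
            return rad / math.sqrt(4 * math.pi)
        comp = zz if axis == "z" else xx
        return math.sqrt(3 / (4 * math.pi)) * comp / rr * rad

    axis = "z" if m == 0 else "x"
    fa = sto(na, la, za, xs, ys, zs, axis)
    fb = sto(nb, lb, zb, xs, ys, zs - r, axis)
    num = np.sum(fa * fb) * dx ** 3
    assert val == pytest.approx(num, abs=2e-4)


def test_overlap_floor_and_decay():
    c = get_element_params("C", "AM1")
    s = I.overlap_blocks(c, c, np.array([[0.0, 0.0, 25.0]]))[0]
    assert np.all(s == 0.0)
    r = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, 6.0], [0.0, 0.0, 9.0]])
    vals = np.abs(I.overlap_blocks(c, c, r)[:, 0, 0])
    assert vals[0] > vals[1] > vals[2]


def test_resonance_is_beta_weighted_overlap():
    c = get_element_params("C", "AM1")
    h = get_element_params("H", "AM1")
    v = np.array([0.0, 0.0, 2.1])
    s = I.overlap_blocks(c, h, v[None])[0]
    res = I.overlap_resonance(c, h, v)
    assert res[0, 0] == pytest.approx(0.5 * (c.beta_s + h.beta_s) * s[0, 0])
    assert res[3, 0] == pytest.approx(0.5 * (c.beta_p + h.beta_s) * s[3, 0])


def test_overlap_rotational_consistency():
    c = get_element_params("C", "AM1")
    o = get_element_params("O", "AM1")
    rng = np.random.default_rng(5)
    v = np.array([1.0, 0.7, -2.2])
    s0 = I.overlap_blocks(c, o, v[None])[0]
    q = rotation(rng)
    s1 = I.overlap_blocks(c, o, (v @ q.T)[None])[0]
    w = np.zeros((4, 4))
    w[0, 0] = 1.0
    w[1:, 1:] = q
    assert np.max(np.abs(w @ s0 @ w.T - s1)) < 1e-10


# -- core-core --------------------------------------------------------------

def test_core_core_symmetry_and_asymptote():
    am1 = [get_element_params(s, "AM1") for s in ("C", "O")]
    v = np.array([0.0, 0.0, 3.1])
    assert I.core_core_energy(*am1, v) == pytest.approx(
        I.core_core_energy(am1[1], am1[0], -v))
    r = 100.0
    c = get_element_params("C", "AM1")
    e = I.core_core_energy(c, c, [0.0, 0.0, r], c_cut=10.0)
    bare = 16.0 * EV_PER_HARTREE / r
    assert e == pytest.approx(bare, rel=1e-9)


def test_core_core_oh_special_form():
    o = get_element_params("O", "MNDO")
    h = get_element_params("H", "MNDO")
    r_b = 1.8
    r_a = r_b * 0.529167
    gam = EV_PER_HARTREE * I.klopman_pair_term(1, 1, r_b, o.rho0, h.rho0)
    expected = 6.0 * gam * (1.0 + r_a * math.exp(-o.alpha * r_a)
                            + math.exp(-h.alpha * r_a))
    assert I.core_core_energy(o, h, [0, 0, r_b]) == pytest.approx(expected)


def test_coincident_atoms_rejected():
    h = get_element_params("H", "AM1")
    with pytest.raises(ValueError, match="coincident"):
        I.core_core_energy(h, h, [0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="coincident"):
        I.eri_block(h, h, [0.0, 0.0, 0.0])
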