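"""Periodic real-space NDDO self-consistent field.

The cyclic-cluster model treats one large supercell with Born-von Karman
boundary conditions, entirely in real space:

* Coulomb (electron-electron, electron-core, core-core) interactions are
  summed over all lattice images out to the screening horizon; beyond ``2α``
  every interaction collapses to the constant radius ``1.5α`` so complete
  neutral cells cancel exactly and the sums terminate;
* exchange interactions for an orbital centered on a given atom are evaluated
  only within the Wigner-Seitz cell around it (the nearest periodic image of
  each partner atom, each pair once);
* the two-electron integrals are Gaussian-damped beyond ``c_cut`` so that
  their small residuals cannot accumulate into unphysical potentials.

A nonperiodic cell reduces exactly to standard gas-phase MNDO/AM1 (no
damping, no screening, all exchange retained).

Closed-shell RHF only; runs are deterministic (fixed diagonal initial guess,
no random numbers anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import integrals as ints
from . import lattice as lat
from .constants import (BOHR_ANGSTROM, DEBYE_PER_E_BOHR, EV_PER_HARTREE,
                        KCAL_PER_EV, angstrom_to_bohr)
from .parameters import get_element_params, valence_electron_count
from .screening import DEFAULT_SCREENING_R


@dataclass(frozen=True)
class SCFOptions:
    """Run controls: tolerances, accelerators, screening/damping radii."""

    screening_r: float = DEFAULT_SCREENING_R   # Å, = 2*alpha
    c_cut: float = ints.DEFAULT_CCUT           # bohr
    tol_energy: float = 1e-6                   # eV
    tol_density: float = 1e-6
    max_iter: int = 200
    damping: float = 0.5        # density mixing for the first iterations
    n_damping: int = 5
    diis_size: int = 8
    enum_margin: float = 2.0    # Å added to the image enumeration radius

    def __post_init__(self):
        if self.screening_r <= 0 or self.c_cut <= 0:
            raise ValueError("screening_r and c_cut must be positive")
        alpha_bohr = angstrom_to_bohr(self.screening_r / 2.0)
        if alpha_bohr <= self.c_cut:
            raise ValueError(
                "screening must engage beyond the damping onset: "
                f"ScreeningR/2 = {alpha_bohr:.2f} bohr <= c_cut = "
                f"{self.c_cut:.2f} bohr")


@dataclass
class SCFState:
    """Converged (or final) SCF data; energies in eV, ΔH_f in kcal/mol."""

    density: np.ndarray
    mo_coeff: np.ndarray
    orbital_energies: np.ndarray
    e_electronic: float
    e_core_core: float
    e_total: float
    heat_formation: float
    n_electrons: int
    converged: bool
    history: list = field(default_factory=list)

    @property
    def n_occupied(self) -> int:
        return self.n_electrons // 2

    @property
    def homo(self) -> float:
        return float(self.orbital_energies[self.n_occupied - 1])

    @property
    def lumo(self) -> float:
        if self.n_occupied >= self.orbital_energies.size:
            raise ValueError("no virtual orbitals")
        return float(self.orbital_energies[self.n_occupied])


def compensated_sum(values) -> float:
    """Neumaier-compensated sum over values ordered by ascending magnitude.

    Stands in for the extended-precision ordered summation needed when many
    small contributions accumulate into a large total.
    """
    vals = np.asarray(list(values), dtype=float).ravel()
    if vals.size == 0:
        return 0.0
    vals = vals[np.argsort(np.abs(vals), kind="stable")]
    total = 0.0
    comp = 0.0
    for v in vals:
        t = total + v
        if abs(total) >= abs(v):
            comp += (total - t) + v
        else:
            comp += (v - t) + total
        total = t
    return total + comp


class _System:
    """Assembled integral tables and core Hamiltonian for one cell."""

    def __init__(self, cell: lat.Cell, hamiltonian: str, options: SCFOptions):
        self.cell = cell
        self.options = options
        self.params = [get_element_params(s, hamiltonian)
                       for s in cell.symbols]
        self.nbas = [p.nbasis for p in self.params]
        self.off = np.concatenate([[0], np.cumsum(self.nbas)])
        self.nbf = int(self.off[-1])
        self.nelec = valence_electron_count(cell, hamiltonian)
        self._assemble()

    # -- geometry / enumeration -------------------------------------------

    def _image_vectors(self):
        cell, opts = self.cell, self.options
        if not cell.periodic:
            return np.zeros((1, 3))
        reach = opts.screening_r + cell.diameter() + opts.enum_margin
        return lat.translations_within(cell, reach)

    def _assemble(self):
        cell, opts = self.cell, self.options
        pos_b = angstrom_to_bohr(cell.positions)
        periodic = cell.periodic
        alpha_b = angstrom_to_bohr(opts.screening_r / 2.0) if periodic else None
        c_cut = opts.c_cut if periodic else None
        ts_b = angstrom_to_bohr(self._image_vectors())
        r2a = 2.0 * alpha_b if periodic else np.inf
        gamma_const = EV_PER_HARTREE / (1.5 * alpha_b) if periodic else 0.0

        n = cell.natoms
        self.pair_J: dict = {}
        self.pair_K: dict = {}
        self.self_J: dict = {}
        h = np.zeros((self.nbf, self.nbf))
        e_nn_terms = []

        # diagonal one-electron energies
        for a, p in enumerate(self.params):
            sl = slice(self.off[a], self.off[a + 1])
            diag = [p.uss] + [p.upp] * (p.nbasis - 1)
            h[sl, sl] += np.diag(diag)

        # minimum-image displacements for exchange / resonance (Å -> bohr)
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        if pairs:
            # orient each pair geometrically (lexicographic on positions) so
            # Wigner-Seitz boundary tie-breaks are permutation invariant
            sgn = np.array([1.0 if tuple(cell.positions[a])
                            <= tuple(cell.positions[b]) else -1.0
                            for a, b in pairs])
            dr0 = np.array([cell.positions[b] - cell.positions[a]
                            for a, b in pairs]) * sgn[:, None]
            dr_min = angstrom_to_bohr(lat.minimum_image(cell, dr0)
                                      if periodic else dr0) * sgn[:, None]
            dmin = np.linalg.norm(dr_min, axis=1)
            if np.any(dmin < 0.5):
                k = int(np.argmin(dmin))
                raise ValueError(
                    f"atoms {pairs[k][0]} and {pairs[k][1]} overlap "
                    f"(minimum-image distance {dmin[k]:.3f} bohr)")

        for k, (a, b) in enumerate(pairs):
            pa, pb = self.params[a], self.params[b]
            rvecs = (pos_b[b] - pos_b[a])[None, :] + ts_b
            r = np.linalg.norm(rvecs, axis=1)
            near = r < r2a
            jsum = np.zeros((pa.nbasis, pa.nbasis, pb.nbasis, pb.nbasis))
            if np.any(near):
                jsum += ints.eri_blocks_images(
                    pa, pb, rvecs[near], alpha=alpha_b, c_cut=c_cut
                ).sum(axis=0)
            nfar = int(np.count_nonzero(~near))
            if nfar:
                ia = np.arange(pa.nbasis)
                ib = np.arange(pb.nbasis)
                jsum[ia[:, None], ia[:, None], ib[None, :], ib[None, :]] \
                    += nfar * gamma_const
            self.pair_J[(a, b)] = jsum
            # exchange/resonance at the Wigner-Seitz (minimum) image only
            kblk = ints.eri_blocks_images(
                pa, pb, dr_min[k][None, :], alpha=alpha_b, c_cut=c_cut)[0]
            self.pair_K[(a, b)] = kblk
            res = ints.resonance_blocks(pa, pb, dr_min[k][None, :])[0]
            sa = slice(self.off[a], self.off[a + 1])
            sb = slice(self.off[b], self.off[b + 1])
            h[sa, sb] += res
            h[sb, sa] += res.T
            # core-core repulsion
            e_nn_terms.append(ints.core_core_energies(
                pa, pb, rvecs[near], alpha=alpha_b, c_cut=c_cut).sum())
            if nfar:
                e_nn_terms.append(
                    pa.z_valence * pb.z_valence * gamma_const * nfar)

        if periodic:
            nonzero = np.linalg.norm(ts_b, axis=1) > 1e-12
            ts_nz = ts_b[nonzero]
            for a, pa in enumerate(self.params):
                r = np.linalg.norm(ts_nz, axis=1)
                near = r < r2a
                jsum = np.zeros((pa.nbasis,) * 4)
                if np.any(near):
                    jsum += ints.eri_blocks_images(
                        pa, pa, ts_nz[near], alpha=alpha_b, c_cut=c_cut
                    ).sum(axis=0)
                nfar = int(np.count_nonzero(~near))
                if nfar:
                    ia = np.arange(pa.nbasis)
                    jsum[ia[:, None], ia[:, None], ia[None, :], ia[None, :]] \
                        += nfar * gamma_const
                self.self_J[a] = jsum
                e_nn_terms.append(0.5 * ints.core_core_energies(
                    pa, pa, ts_nz[near], alpha=alpha_b, c_cut=c_cut).sum())
                if nfar:
                    e_nn_terms.append(
                        0.5 * pa.z_valence ** 2 * gamma_const * nfar)

        # electron-core attraction V_{μν,B} = -Z_B (μν|s_B s_B), all images
        for (a, b), jsum in self.pair_J.items():
            sa = slice(self.off[a], self.off[a + 1])
            sb = slice(self.off[b], self.off[b + 1])
            h[sa, sa] += -self.params[b].z_valence * jsum[:, :, 0, 0]
            h[sb, sb] += -self.params[a].z_valence * jsum[0, 0, :, :]
        for a, jsum in self.self_J.items():
            sa = slice(self.off[a], self.off[a + 1])
            h[sa, sa] += -self.params[a].z_valence * jsum[:, :, 0, 0]

        self.h_core = 0.5 * (h + h.T)
        self.e_core_core = compensated_sum(e_nn_terms)

    # -- Fock build --------------------------------------------------------

    def build_fock(self, p: np.ndarray) -> np.ndarray:
        f = self.h_core.copy()
        off = self.off
        # one-center two-electron terms
        for a, pp in enumerate(self.params):
            sl = slice(off[a], off[a + 1])
            pa = p[sl, sl]
            fa = np.zeros_like(pa)
            fa[0, 0] = 0.5 * pa[0, 0] * pp.gss
            if pp.nbasis == 4:
                pdiag = np.diag(pa)[1:]
                fa[0, 0] += np.sum(pdiag) * (pp.gsp - 0.5 * pp.hsp)
                for i in range(1, 4):
                    fa[i, i] = (0.5 * pa[i, i] * pp.gpp
                                + pa[0, 0] * (pp.gsp - 0.5 * pp.hsp)
                                + (np.sum(pdiag) - pa[i, i])
                                * (1.25 * pp.gp2 - 0.25 * pp.gpp))
                    fa[0, i] = pa[0, i] * (1.5 * pp.hsp - 0.5 * pp.gsp)
                    fa[i, 0] = fa[0, i]
                    for j in range(i + 1, 4):
                        fa[i, j] = pa[i, j] * (1.5 * pp.hpp - 0.5 * pp.gp2)
                        fa[j, i] = fa[i, j]
            f[sl, sl] += fa
        # two-center Coulomb (all images) and Wigner-Seitz exchange
        for (a, b), j in self.pair_J.items():
            sa = slice(off[a], off[a + 1])
            sb = slice(off[b], off[b + 1])
            f[sa, sa] += np.einsum("ijkl,kl->ij", j, p[sb, sb])
            f[sb, sb] += np.einsum("ijkl,ij->kl", j, p[sa, sa])
            k = self.pair_K[(a, b)]
            f[sa, sb] -= 0.5 * np.einsum("mnls,ns->ml", k, p[sa, sb])
            f[sb, sa] = f[sa, sb].T
        for a, j in self.self_J.items():
            sa = slice(off[a], off[a + 1])
            f[sa, sa] += np.einsum("ijkl,kl->ij", j, p[sa, sa])
        return 0.5 * (f + f.T)

    def electronic_energy(self, p, f) -> float:
        return 0.5 * float(np.vdot(p, self.h_core + f).real)

    def electronic_energy_compensated(self, p, f) -> float:
        return compensated_sum(0.5 * p * (self.h_core + f))


def build_core_hamiltonian(cell, hamiltonian="AM1", options=None):
    """Core Hamiltonian (eV): U diagonal, minimum-image resonance, screened
    and damped electron-core attraction summed over lattice images."""
    return _System(cell, hamiltonian, options or SCFOptions()).h_core


def build_fock(p, cell, hamiltonian="AM1", options=None):
    """Fock matrix (eV) for density ``p`` (standalone convenience wrapper)."""
    return _System(cell, hamiltonian, options or SCFOptions()).build_fock(p)


class _DIIS:
    def __init__(self, size):
        self.size = size
        self.focks: list = []
        self.errors: list = []

    def push(self, f, err):
        self.focks.append(f)
        self.errors.append(err.ravel())
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errors.pop(0)

    def extrapolate(self):
        m = len(self.focks)
        if m < 2:
            return self.focks[-1]
        b = -np.ones((m + 1, m + 1))
        b[m, m] = 0.0
        for i in range(m):
            for j in range(m):
                b[i, j] = self.errors[i] @ self.errors[j]
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        try:
            coef = np.linalg.solve(b, rhs)[:m]
        except np.linalg.LinAlgError:
            return self.focks[-1]
        return sum(c * f for c, f in zip(coef, self.focks))


def _density_from_fock(f, nocc):
    eps, c = scipy.linalg.eigh(f)
    p = 2.0 * c[:, :nocc] @ c[:, :nocc].T
    return p, eps, c


def scf_run(cell, hamiltonian="AM1", options=None) -> SCFState:
    """Run the SCF to convergence (max |ΔP| and |ΔE| below tolerance).

    Deterministic: diagonal atomic-density initial guess, fixed damping for
    the first iterations, then DIIS.  Raises for open shells and for charged
    periodic cells; returns an unconverged state (flagged) after ``max_iter``.
    """
    options = options or SCFOptions()
    if cell.periodic and cell.charge != 0:
        raise ValueError("periodic cells must be neutral")
    system = _System(cell, hamiltonian, options)
    if system.nelec % 2:
        raise ValueError(
            f"open shell unsupported ({system.nelec} valence electrons)")
    nocc = system.nelec // 2
    if nocc > system.nbf:
        raise ValueError("more electron pairs than basis functions")

    p = np.zeros((system.nbf, system.nbf))
    for a, pp in enumerate(system.params):
        sl = slice(system.off[a], system.off[a + 1])
        p[sl, sl] = np.eye(pp.nbasis) * (pp.z_valence / pp.nbasis)

    diis = _DIIS(options.diis_size)
    e_old = np.inf
    history = []
    converged = False
    eps = np.zeros(system.nbf)
    c = np.eye(system.nbf)
    for it in range(1, options.max_iter + 1):
        f = system.build_fock(p)
        err = f @ p - p @ f
        e_elec = system.electronic_energy(p, f)
        e_tot = e_elec + system.e_core_core
        diis.push(f, err)
        if it > options.n_damping:
            f_eff = diis.extrapolate()
        else:
            f_eff = f
        p_new, eps, c = _density_from_fock(f_eff, nocc)
        if it <= options.n_damping:
            p_new = (1.0 - options.damping) * p_new + options.damping * p
        dp = float(np.max(np.abs(p_new - p)))
        de = abs(e_tot - e_old)
        history.append((e_tot, dp))
        p, e_old = p_new, e_tot
        if dp < options.tol_density and de < options.tol_energy and it > 1:
            converged = True
            break

    f = system.build_fock(p)
    e_elec = system.electronic_energy_compensated(p, f)
    e_tot = e_elec + system.e_core_core
    state = SCFState(
        density=p, mo_coeff=c, orbital_energies=eps,
        e_electronic=e_elec, e_core_core=system.e_core_core, e_total=e_tot,
        heat_formation=np.nan, n_electrons=system.nelec,
        converged=converged, history=history)
    if converged:
        state.heat_formation = heat_of_formation(state, cell, system.params)
    return state


def heat_of_formation(state: SCFState, cell, params=None,
                      hamiltonian="AM1") -> float:
    """Semiempirical heat of formation, kcal/mol.

    ΔH_f = (E_elec + E_core-core - Σ_A E_isol(A)) · 23.061 + Σ_A ΔH_f,atom(A).
    """
    if not state.converged:
        raise ValueError("refusing heat of formation from unconverged state")
    if params is None:
        params = [get_element_params(s, hamiltonian) for s in cell.symbols]
    e_isol = compensated_sum([p.eisol for p in params])
    e_atoms = compensated_sum([p.eheat for p in params])
    return (state.e_total - e_isol) * KCAL_PER_EV + e_atoms


def coulson_charges(state: SCFState, cell, hamiltonian="AM1") -> np.ndarray:
    """Coulson population charges q_A = Z_v(A) - Σ_{μ∈A} P_μμ (e)."""
    params = [get_element_params(s, hamiltonian) for s in cell.symbols]
    diag = np.diag(state.density)
    out = np.empty(cell.natoms)
    k = 0
    for a, p in enumerate(params):
        out[a] = p.z_valence - diag[k:k + p.nbasis].sum()
        k += p.nbasis
    return out


def dipole_moment(state: SCFState, cell, hamiltonian="AM1") -> np.ndarray:
    """Dipole moment vector (Debye) of a nonperiodic cell: point-charge part
    plus the sp hybridization contribution -2 D1 P_sp per atom."""
    if cell.periodic:
        raise ValueError("dipole moment defined for nonperiodic cells only")
    params = [get_element_params(s, hamiltonian) for s in cell.symbols]
    q = coulson_charges(state, cell, hamiltonian)
    mu = (q[:, None] * angstrom_to_bohr(cell.positions)).sum(axis=0)
    k = 0
    for p in params:
        if p.nbasis == 4:
            psp = state.density[k, k + 1:k + 4]
            mu = mu - 2.0 * p.d1 * psp
        k += p.nbasis
    return mu * DEBYE_PER_E_BOHR
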