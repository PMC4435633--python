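"""Real-space local-property grids: electron density, molecular electrostatic
potential (MEP), local ionization energy (IE_L) and local electron affinity
(EA_L), with cube-file export and slice extraction.

Grid values are computed from the converged SCF state: MO-based densities use
the orthogonal-basis MO coefficients applied directly to the Slater basis
functions (a documented approximation — no deorthogonalization step), and the
MEP uses the same distributed-multipole, screened, damped machinery as the
energy, so the potential is consistent with the Hamiltonian rather than with
a point-charge model.

IE_L(r) = -Σ_occ ρ_i(r) ε_i / Σ_occ ρ_i(r) and, with the ``orbital_density``
weighting variant adopted here, EA_L(r) = -Σ_virt ρ_a(r) ε_a / Σ_virt ρ_a(r);
electronegativity (IE_L+EA_L)/2 and hardness (IE_L-EA_L)/2 are provided as
derived grids.  In the condensed phase IE_L and EA_L map the local
valence-band maximum and conduction-band minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lattice as lat
from .constants import (BOHR_ANGSTROM, EV_PER_HARTREE, KCAL_PER_EV,
                        angstrom_to_bohr)
from .integrals import _damping_factor, multipole_charge_sets, \
    rotation_matrices
from .parameters import get_element_params
from .screening import effective_distance, multipole_contraction
from .scf import SCFOptions, SCFState

#: adopted EA_L weighting variant (see module docstring)
EA_WEIGHTING = "orbital_density"

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9,
                 "Na": 11, "P": 15, "S": 16, "Cl": 17, "Zn": 30}

GRID_KINDS = ("density", "mep", "ie_local", "ea_local",
              "electronegativity", "hardness")

#: basis functions are evaluated out to this range (bohr)
BASIS_RANGE = 12.0


@dataclass(frozen=True)
class PropertyGrid:
    """Regular real-space grid of one local property over the cell.

    ``origin`` (Å), three step ``axes`` (Å, rows), integer ``shape`` and the
    value array of that shape (units: e/Å^3 for density, kcal/mol for the
    energy-like properties).
    """

    origin: np.ndarray
    axes: np.ndarray            # (3, 3) step vectors, Å
    values: np.ndarray          # shape (n1, n2, n3)
    kind: str = ""

    def __post_init__(self):
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "axes",
                           np.asarray(self.axes, dtype=float).reshape(3, 3))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 3 or min(vals.shape) < 2:
            raise ValueError("grid needs >= 2 points per axis")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite grid values")

    @property
    def shape(self):
        return self.values.shape

    def points(self) -> np.ndarray:
        """All grid points, array (n1, n2, n3, 3) in Å."""
        n1, n2, n3 = self.shape
        i, j, k = np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3),
                              indexing="ij")
        idx = np.stack([i, j, k], axis=-1).astype(float)
        return self.origin + idx @ self.axes


def grid_points(cell: lat.Cell, shape, origin=None, extent=None):
    """Build grid geometry: for periodic axes the grid spans exactly one
    lattice vector (endpoint exclusive); nonperiodic axes span the bounding
    box plus a margin (or an explicit cubic ``extent``)."""
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 2:
        raise ValueError("grid shape must give >= 2 points per axis")
    axes = np.zeros((3, 3))
    if origin is None:
        origin = np.zeros(3)
    if cell.periodic:
        for d in range(cell.ndim):
            axes[d] = cell.lattice[d] / shape[d]
    lo = cell.positions.min(axis=0)
    hi = cell.positions.max(axis=0)
    margin = 4.0
    for d in range(cell.ndim, 3):
        if extent is not None:
            length = float(extent)
            start = cell.positions.mean(axis=0)[d] - length / 2.0
        else:
            length = hi[d] - lo[d] + 2 * margin
            start = lo[d] - margin
        e = np.zeros(3)
        e[d] = length / shape[d]
        axes[d] = e
        origin = np.asarray(origin, dtype=float).copy()
        origin[d] = start
    return np.asarray(origin, dtype=float), axes


def _basis_values(cell, params, points_ang):
    """Slater basis values at the points (nbf, npts), minimum-image atoms."""
    from math import factorial, sqrt
    pts = np.asarray(points_ang, dtype=float).reshape(-1, 3)
    nbf = sum(p.nbasis for p in params)
    out = np.zeros((nbf, pts.shape[0]))
    k = 0
    for a, p in enumerate(params):
        dr = pts - cell.positions[a]
        if cell.periodic:
            dr = lat.minimum_image(cell, dr)
        dr_b = angstrom_to_bohr(dr)
        r = np.linalg.norm(dr_b, axis=1)
        near = r < BASIS_RANGE
        rn = np.where(near, r, 1.0)
        for (n, zeta, l) in ([(p.n_principal, p.zeta_s, 0)]
                             + ([(p.n_principal, p.zeta_p, 1)]
                                if p.nbasis == 4 else [])):
            norm = (2 * zeta) ** (n + 0.5) / sqrt(factorial(2 * n))
            rad = np.where(near, norm * rn ** (n - 1) * np.exp(-zeta * rn),
                           0.0)
            if l == 0:
                out[k] = rad / sqrt(4 * np.pi)
                k += 1
            else:
                ang = sqrt(3.0 / (4 * np.pi)) * dr_b / np.where(
                    rn[:, None] > 1e-12, rn[:, None], 1.0)
                for i in range(3):
                    out[k + i] = rad * ang[:, i]
                k += 3
    return out


def _orbital_densities(state, cell, params, pts, indices):
    phi = _basis_values(cell, params, pts)          # (nbf, npts)
    psi = state.mo_coeff[:, indices].T @ phi        # (nmo, npts)
    return psi * psi


def _mep_values(state, cell, params, pts_ang, options: SCFOptions):
    """Screened distributed-multipole electrostatic potential, hartree/e."""
    pts_b = angstrom_to_bohr(np.asarray(pts_ang, dtype=float).reshape(-1, 3))
    pos_b = angstrom_to_bohr(cell.positions)
    periodic = cell.periodic
    alpha_b = angstrom_to_bohr(options.screening_r / 2) if periodic else None
    c_cut = options.c_cut if periodic else None
    if periodic:
        reach = options.screening_r + cell.diameter() + options.enum_margin
        ts = angstrom_to_bohr(lat.translations_within(cell, reach))
    else:
        ts = np.zeros((1, 3))
    v = np.zeros(pts_b.shape[0])
    off = 0
    for a, p in enumerate(params):
        nb = p.nbasis
        pblock = state.density[off:off + nb, off:off + nb]
        off += nb
        pairs = [(0, 0)] if nb == 1 else [(i, j) for i in range(4)
                                          for j in range(i, 4)]
        comps = {pr: multipole_charge_sets(p, pr) for pr in pairs}
        for t in ts:
            d = pts_b - (pos_b[a] + t)
            r = np.linalg.norm(d, axis=1)
            r = np.maximum(r, 1e-6)
            if alpha_b is not None:
                reff = effective_distance(r, alpha_b)
                lam = multipole_contraction(r, alpha_b)
            else:
                reff, lam = r, np.ones_like(r)
            f = _damping_factor(r, c_cut)
            # core: the ss monopole kernel (consistent with V_μν)
            v += p.z_valence / np.sqrt(reff ** 2 + (f * p.rho0) ** 2)
            # electrons: rotate the density block into the local frame of
            # each point and contract with the canonical charge sets
            u = d / r[:, None]
            w = rotation_matrices(u)[:, :nb, :nb]
            ploc = np.einsum("nim,ij,njl->nml", w, pblock, w)
            for (i, j), sets in comps.items():
                weight = ploc[:, i, j] * (1.0 if i == j else 2.0)
                for cs in sets:
                    seff = f * cs.rho
                    for q, ofs in cs.charges:
                        # probe sits at +reff on the local z axis; a charge
                        # offset +ofs_z toward it shortens the separation
                        dz = -ofs[2] * lam
                        m2 = (ofs[0] ** 2 + ofs[1] ** 2 + ofs[2] ** 2) \
                            * lam ** 2
                        dist2 = reff ** 2 + 2 * reff * dz + m2
                        v -= weight * q / np.sqrt(dist2 + seff * seff)
    return v


def local_property_grid(state: SCFState, cell: lat.Cell, kind: str,
                        grid_spec=(16, 16, 16), hamiltonian: str = "AM1",
                        options: SCFOptions | None = None,
                        origin=None, extent=None) -> PropertyGrid:
    """Evaluate a local property on a regular grid over the cell.

    ``grid_spec`` is the point count per axis.  Density in e/Å^3; MEP, IE_L,
    EA_L, electronegativity and hardness in kcal/mol.
    """
    if not state.converged:
        raise ValueError("local properties require a converged SCF state")
    if kind not in GRID_KINDS:
        raise ValueError(f"unknown property kind {kind!r}; "
                         f"choose from {GRID_KINDS}")
    options = options or SCFOptions()
    params = [get_element_params(s, hamiltonian) for s in cell.symbols]
    origin, axes = grid_points(cell, grid_spec, origin=origin, extent=extent)
    shape = tuple(int(n) for n in grid_spec)
    grid = PropertyGrid(origin, axes, np.zeros(shape), kind=kind)
    pts = grid.points().reshape(-1, 3)
    vals = evaluate_property(state, cell, kind, pts,
                             hamiltonian=hamiltonian, options=options,
                             params=params)
    return PropertyGrid(origin, axes, vals.reshape(shape), kind=kind)


def evaluate_property(state, cell, kind, pts, hamiltonian="AM1",
                      options=None, params=None):
    """Pointwise evaluation backing :func:`local_property_grid` (same units)."""
    options = options or SCFOptions()
    if params is None:
        params = [get_element_params(s, hamiltonian) for s in cell.symbols]
    nocc = state.n_occupied
    nmo = state.orbital_energies.size
    if kind == "density":
        # ZDO-consistent density: only the retained monatomic orbital
        # products contribute, so the grid integrates to N_elec exactly and
        # the diagonal-block quadratic form keeps it non-negative
        phi = _basis_values(cell, params, pts)
        vals = np.zeros(phi.shape[1])
        k = 0
        for p in params:
            nb = p.nbasis
            blk = state.density[k:k + nb, k:k + nb]
            vals += np.einsum("ip,ij,jp->p", phi[k:k + nb], blk,
                              phi[k:k + nb])
            k += nb
        vals = vals / BOHR_ANGSTROM ** 3                     # e / Å^3
    elif kind == "mep":
        vals = _mep_values(state, cell, params, pts, options) \
            * EV_PER_HARTREE * KCAL_PER_EV
    elif kind in ("ie_local", "ea_local", "electronegativity", "hardness"):
        def weighted(indices):
            if len(indices) == 0:
                raise ValueError(f"no orbitals available for {kind}")
            dens = _orbital_densities(state, cell, params, pts, indices)
            eps = state.orbital_energies[indices]
            num = -(eps[:, None] * dens).sum(axis=0)
            den = dens.sum(axis=0)
            # where every orbital density underflows (far outside the basis
            # range) the weighted mean is 0/0; use the frontier-orbital limit
            dead = den < 1e-250
            out = np.where(dead, -eps[-1 if indices[0] < nocc else 0],
                           num / np.where(dead, 1.0, den))
            return out * KCAL_PER_EV
        if kind == "ie_local":
            vals = weighted(np.arange(nocc))
        elif kind == "ea_local":
            vals = weighted(np.arange(nocc, nmo))
        else:
            ie = weighted(np.arange(nocc))
            ea = weighted(np.arange(nocc, nmo))
            vals = 0.5 * (ie + ea) if kind == "electronegativity" \
                else 0.5 * (ie - ea)
    else:
        raise ValueError(f"unknown property kind {kind!r}")
    return vals


def extract_slice(grid: PropertyGrid, axis: int, index: int):
    """2-D field at ``index`` along ``axis`` (1, 2 or 3).

    Returns ``(values_2d, in_plane_axes)``; values are unchanged, so stacking
    all indices reproduces the grid exactly.
    """
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    n = grid.shape[axis - 1]
    if not (0 <= index < n):
        raise IndexError(f"slice index {index} outside 0..{n - 1}")
    vals = np.take(grid.values, index, axis=axis - 1)
    in_plane = np.delete(np.arange(3), axis - 1)
    return vals, grid.axes[in_plane]


# --------------------------------------------------------------------------
# Gaussian cube files
# --------------------------------------------------------------------------

def write_cube(path, grid: PropertyGrid, cell: lat.Cell):
    """Write a standard Gaussian cube file (header in bohr, z-fastest data)."""
    with open(path, "w") as fh:
        fh.write(f"semicell {grid.kind or 'property'} grid\n")
        fh.write("outer loop x, middle y, inner z\n")
        o = angstrom_to_bohr(grid.origin)
        fh.write(f"{cell.natoms:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        for d in range(3):
            ax = angstrom_to_bohr(grid.axes[d])
            fh.write(f"{grid.shape[d]:5d} {ax[0]:12.6f} {ax[1]:12.6f} "
                     f"{ax[2]:12.6f}\n")
        for sym, pos in zip(cell.symbols, cell.positions):
            z = ATOMIC_NUMBER[sym]
            p = angstrom_to_bohr(pos)
            fh.write(f"{z:5d} {float(z):12.6f} {p[0]:12.6f} {p[1]:12.6f} "
                     f"{p[2]:12.6f}\n")
        flat = grid.values.reshape(grid.shape[0], -1)
        for row in flat:
            for k in range(0, row.size, 6):
                fh.write(" ".join(f"{v: .6e}" for v in row[k:k + 6]) + "\n")


def read_cube(path):
    """Read a cube file written by :func:`write_cube`.

    Returns ``(grid, symbols, positions_ang)``.
    """
    inv_z = {v: k for k, v in ATOMIC_NUMBER.items()}
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = BOHR_ANGSTROM * np.array([float(x) for x in parts[1:4]])
        shape, axes = [], []
        for _ in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            axes.append([BOHR_ANGSTROM * float(x) for x in parts[1:4]])
        symbols, positions = [], []
        for _ in range(natoms):
            parts = fh.readline().split()
            symbols.append(inv_z[int(parts[0])])
            positions.append([BOHR_ANGSTROM * float(x) for x in parts[2:5]])
        data = np.array(fh.read().split(), dtype=float).reshape(shape)
    grid = PropertyGrid(origin, np.array(axes), data)
    return grid, tuple(symbols), np.array(positions)


def write_slice_tsv(path, values2d, axes2):
    """Export a slice as tab-separated text (row/col indices + value)."""
    with open(path, "w") as fh:
        fh.write("# in-plane axes (Å):"
                 + " ".join(f"{x:.6f}" for x in np.ravel(axes2)) + "\n")
        for i, row in enumerate(np.asarray(values2d)):
            fh.write("\t".join(f"{v:.8e}" for v in row) + "\n")
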