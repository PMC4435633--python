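"""Unit-cell geometry for the cyclic-cluster model.

A :class:`Cell` is a single real-space supercell with 0-3 periodic lattice
vectors (Born-von Karman boundary conditions, no k-point sampling).  The
module provides the nearest-image metric, Wigner-Seitz membership (the zone
inside which exchange interactions are retained), lattice-image enumeration
for the screened electrostatic sums, and programmatic crystal fixtures.

Conventions: Cartesian Å throughout; lattice rows are vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

#: half-width of the translation search block per periodic direction
_SHELL = 2
#: tolerance (Å) below which two image norms count as tied
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class Cell:
    """Atoms plus 0-3 lattice vectors; the single cyclic-cluster supercell."""

    symbols: tuple
    positions: np.ndarray          # (n, 3) Å
    lattice: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    charge: int = 0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        lat = np.asarray(self.lattice, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lattice", lat)
        if len(self.symbols) != len(pos) or len(pos) < 1:
            raise ValueError("need one position per element symbol, >= 1 atom")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite atom position")
        if lat.shape[0] > 3:
            raise ValueError("at most 3 lattice vectors")
        if lat.shape[0]:
            gram = lat @ lat.T
            if np.linalg.det(gram) <= 1e-12:
                raise ValueError("lattice vectors must be linearly independent")

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def ndim(self) -> int:
        """Periodic dimensionality (0-3)."""
        return self.lattice.shape[0]

    @property
    def periodic(self) -> bool:
        return self.ndim > 0

    def diameter(self) -> float:
        """Length of the longest cell body diagonal (0 for molecules)."""
        if not self.periodic:
            return 0.0
        corners = np.array(list(itertools.product(*[(0.0, 1.0)] * self.ndim)))
        return float(max(np.linalg.norm(c @ self.lattice) for c in corners))

    def with_charge(self, charge: int) -> "Cell":
        return replace(self, charge=charge)


def _skew_shell(cell: Cell) -> int:
    """Widen the image search for cells with any angle below 45 degrees."""
    lat = cell.lattice
    n = lat.shape[0]
    shell = _SHELL
    for i in range(n):
        for j in range(i + 1, n):
            c = abs(lat[i] @ lat[j]) / (
                np.linalg.norm(lat[i]) * np.linalg.norm(lat[j]))
            if c > np.cos(np.pi / 4):
                shell = max(shell, 4)
    return shell


def _candidate_translations(cell: Cell) -> np.ndarray:
    shell = _skew_shell(cell)
    rng = range(-shell, shell + 1)
    combos = np.array(list(itertools.product(*[rng] * cell.ndim)), dtype=float)
    return combos @ cell.lattice


def _canonical_index(vecs: np.ndarray) -> int:
    """Index of the canonical minimum-norm vector (lexicographic tie-break).

    Among candidates within ``_TIE_TOL`` of the smallest norm the
    lexicographically greatest (x, then y, then z) vector wins, so exactly one
    image of a Wigner-Seitz boundary point is accepted.
    """
    norms = np.linalg.norm(vecs, axis=1)
    tied = np.flatnonzero(norms <= norms.min() + _TIE_TOL)
    best = tied[0]
    for i in tied[1:]:
        if tuple(vecs[i]) > tuple(vecs[best]):
            best = i
    return int(best)


def minimum_image(cell: Cell, dr):
    """Map displacement(s) Δr (Å) to the nearest periodic image.

    Components along non-periodic directions are unchanged; for a nonperiodic
    cell this is the identity.  Accepts a single vector or an (n, 3) array.
    """
    dr = np.asarray(dr, dtype=float)
    single = dr.ndim == 1
    vecs = dr.reshape(-1, 3).copy()
    if cell.periodic:
        lat = cell.lattice
        gram = lat @ lat.T
        frac = np.linalg.solve(gram, lat @ vecs.T).T       # (n, d)
        base = -np.round(frac) @ lat
        cand_t = _candidate_translations(cell)
        for k in range(vecs.shape[0]):
            trial = vecs[k] + base[k] + cand_t
            vecs[k] = trial[_canonical_index(trial)]
    return vecs[0] if single else vecs


def in_wigner_seitz(cell: Cell, dr) -> bool:
    """True iff Δr lies in the Wigner-Seitz cell around the origin.

    Boundary ties are broken so that exactly one lattice image of any point is
    accepted (see :func:`minimum_image`).
    """
    if not cell.periodic:
        return True
    dr = np.asarray(dr, dtype=float).reshape(3)
    mi = minimum_image(cell, dr)
    return bool(np.all(np.abs(mi - dr) < 1e-9))


def lattice_images_within(cell: Cell, r_max: float) -> np.ndarray:
    """All lattice translations with |T| ≤ r_max + cell diameter.

    Includes the zero translation; ordered by |T| with lexicographic
    tie-break, so the zero translation comes first.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if not cell.periodic:
        return np.zeros((1, 3))
    reach = r_max + max(np.linalg.norm(cell.lattice, axis=1))
    return translations_within(cell, reach)


def translations_within(cell: Cell, radius: float) -> np.ndarray:
    """Lattice translations T with |T| ≤ radius, zero first, deterministic."""
    if not cell.periodic:
        return np.zeros((1, 3))
    lat = cell.lattice
    gram = lat @ lat.T
    inv = np.linalg.inv(gram)
    # distance between lattice planes normal to a_i is 1/|row_i of inv @ lat|
    nmax = [int(np.floor(radius * np.sqrt(inv[i, i]))) + 1
            for i in range(cell.ndim)]
    rngs = [range(-m, m + 1) for m in nmax]
    combos = np.array(list(itertools.product(*rngs)), dtype=float)
    ts = combos @ lat
    norms = np.linalg.norm(ts, axis=1)
    keep = norms <= radius + 1e-12
    ts, norms = ts[keep], norms[keep]
    order = np.lexsort((ts[:, 2], ts[:, 1], ts[:, 0], np.round(norms, 9)))
    return ts[order]


def supercell_expand(cell: Cell, repeat) -> Cell:
    """Replicate a periodic cell n1 x n2 x n3 (trailing factors ignored for
    lower periodicity); element ordering is deterministic (cell-major)."""
    repeat = tuple(int(r) for r in repeat)[: cell.ndim]
    if not cell.periodic or all(r == 1 for r in repeat):
        return cell
    if any(r < 1 for r in repeat):
        raise ValueError("repeat factors must be >= 1")
    combos = itertools.product(*[range(r) for r in repeat])
    symbols, positions = [], []
    for combo in combos:
        shift = np.array(combo, dtype=float) @ cell.lattice
        symbols.extend(cell.symbols)
        positions.append(cell.positions + shift)
    lat = cell.lattice * np.array(repeat, dtype=float)[:, None]
    return Cell(tuple(symbols), np.vstack(positions), lat, cell.charge)


# --- programmatic crystal and molecular fixtures ---------------------------

#: default lattice constants (Å) — standard literature values, overridable
DIAMOND_A = 3.567
ROCKSALT_A = 5.64
WURTZITE_A = 3.25
WURTZITE_C = 5.207
WURTZITE_U = 0.382

#: gas-phase water used by the molecular-box fixture (Å)
WATER = (("O", "H", "H"),
         np.array([[0.000000, 0.000000, 0.000000],
                   [0.957200, 0.000000, 0.000000],
                   [-0.239988, 0.926627, 0.000000]]))


def _from_fractional(symbols, frac, lattice, charge=0) -> Cell:
    return Cell(tuple(symbols), np.asarray(frac) @ lattice,
                np.asarray(lattice, dtype=float), charge)


def build_crystal_fixture(kind: str, repeat=(1, 1, 1), *, a=None, c=None,
                          molecule=None, box=None) -> Cell:
    """Generate a conventional-cell crystal (or molecular box) fixture.

    kinds: ``diamond`` (8-atom cubic C cell), ``rocksalt`` (8-atom Na4Cl4),
    ``wurtzite`` (4-atom ZnO cell), ``molecular_box`` (molecule on a cubic
    grid; default one water in a 10 Å box).
    """
    if kind == "diamond":
        a = DIAMOND_A if a is None else a
        fcc = [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)]
        frac = [f for f in fcc] + [tuple(x + .25 for x in f) for f in fcc]
        cell = _from_fractional(["C"] * 8, frac, np.eye(3) * a)
    elif kind == "rocksalt":
        a = ROCKSALT_A if a is None else a
        fcc = [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)]
        frac = fcc + [tuple(x + .5 for x in f[:1]) + f[1:] for f in fcc]
        cell = _from_fractional(["Na"] * 4 + ["Cl"] * 4, frac, np.eye(3) * a)
    elif kind == "wurtzite":
        a = WURTZITE_A if a is None else a
        c = WURTZITE_C if c is None else c
        u = WURTZITE_U
        lat = np.array([[a, 0, 0],
                        [-a / 2, a * np.sqrt(3) / 2, 0],
                        [0, 0, c]])
        frac = [(1 / 3, 2 / 3, 0.0), (2 / 3, 1 / 3, 0.5),
                (1 / 3, 2 / 3, u), (2 / 3, 1 / 3, 0.5 + u)]
        cell = _from_fractional(["Zn", "Zn", "O", "O"], frac, lat)
    elif kind == "molecular_box":
        syms, pos = WATER if molecule is None else molecule
        box = 10.0 if box is None else float(box)
        if box <= 0:
            raise ValueError("box length must be positive")
        pos = np.asarray(pos, dtype=float)
        center = box / 2 - pos.mean(axis=0)
        cell = Cell(tuple(syms), pos + center, np.eye(3) * box)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    if a is not None and a <= 0 or (c is not None and c <= 0):
        raise ValueError("lattice constants must be positive")
    return supercell_expand(cell, repeat)
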