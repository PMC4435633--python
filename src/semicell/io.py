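"""File formats and run configuration.

Structures are exchanged as extended-XYZ: element symbol + Cartesian Å per
line, with an optional ``Lattice="..."`` record on the comment line carrying
3, 6 or 9 numbers — one row of three per periodic direction, so 1-, 2- and
3-D periodicity are expressed by the number of lattice vectors.  Run options
come from a plain ``keyword value`` text file (or CLI flags, which win);
``ScreeningR`` follows the convention that its value is ``2α`` in Å.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Cell
from .parameters import SUPPORTED_ELEMENTS, get_element_params
from .scf import SCFOptions
from .screening import DEFAULT_SCREENING_R


# --------------------------------------------------------------------------
# extended-XYZ
# --------------------------------------------------------------------------

def _parse_comment_fields(line: str) -> dict:
    fields = {}
    for token in shlex.split(line):
        if "=" in token:
            key, val = token.split("=", 1)
            fields[key.lower()] = val
    return fields


def read_structure(path) -> Cell:
    """Read an extended-XYZ file into a :class:`Cell`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed atom-count line {lines[0]!r}")
    if len(lines) < natoms + 2:
        raise ValueError(f"{path}: expected {natoms} atom lines")
    fields = _parse_comment_fields(lines[1]) if len(lines) > 1 else {}
    lattice = np.zeros((0, 3))
    if "lattice" in fields:
        nums = [float(x) for x in fields["lattice"].split()]
        if len(nums) not in (3, 6, 9):
            raise ValueError(
                f"{path}: lattice record needs 3, 6 or 9 numbers, "
                f"got {len(nums)}")
        lattice = np.array(nums).reshape(-1, 3)
    charge = int(float(fields.get("charge", "0")))
    symbols, positions = [], []
    for line in lines[2:2 + natoms]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {line!r}")
        sym = parts[0].capitalize()
        if sym not in SUPPORTED_ELEMENTS:
            raise ValueError(f"{path}: unknown element {parts[0]!r}")
        symbols.append(sym)
        positions.append([float(x) for x in parts[1:4]])
    return Cell(tuple(symbols), np.array(positions), lattice, charge)


def write_structure(cell: Cell, path):
    """Write extended-XYZ with a lattice record iff the cell is periodic;
    deterministic fixed-precision formatting."""
    with open(path, "w") as fh:
        fh.write(f"{cell.natoms}\n")
        comment = ['Properties=species:S:1:pos:R:3']
        if cell.periodic:
            nums = " ".join(f"{x:.10f}" for x in cell.lattice.ravel())
            comment.insert(0, f'Lattice="{nums}"')
        if cell.charge:
            comment.append(f"Charge={cell.charge}")
        fh.write(" ".join(comment) + "\n")
        for sym, pos in zip(cell.symbols, cell.positions):
            fh.write(f"{sym:2s} {pos[0]:18.10f} {pos[1]:18.10f} "
                     f"{pos[2]:18.10f}\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_KEYWORDS = {
    "hamiltonian": str,
    "screeningr": float,
    "ccut": float,
    "scftole": float,
    "scftolp": float,
    "maxiter": int,
    "gridshape": str,
    "charge": int,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated keyword configuration of one run."""

    hamiltonian: str = "AM1"
    screening_r: float = DEFAULT_SCREENING_R   # Å, = 2α
    c_cut: float = 10.0                        # bohr
    tol_energy: float = 1e-6
    tol_density: float = 1e-6
    max_iter: int = 200
    grid_shape: tuple = (16, 16, 16)
    charge: int = 0

    def __post_init__(self):
        if self.hamiltonian.upper() not in ("MNDO", "AM1"):
            raise ValueError(
                f"Hamiltonian must be MNDO or AM1, got {self.hamiltonian!r}")
        object.__setattr__(self, "hamiltonian", self.hamiltonian.upper())
        # delegates radius invariants (ScreeningR/2 in bohr > c_cut)
        self.scf_options()

    @property
    def alpha(self) -> float:
        """Screening α in Å (ScreeningR stores 2α; converted only here)."""
        return self.screening_r / 2.0

    def scf_options(self) -> SCFOptions:
        return SCFOptions(screening_r=self.screening_r, c_cut=self.c_cut,
                          tol_energy=self.tol_energy,
                          tol_density=self.tol_density,
                          max_iter=self.max_iter)


def parse_config(path=None, **overrides) -> RunConfig:
    """Parse ``keyword value`` config text; keyword arguments override the
    file.  Unknown keywords raise with the list of valid ones."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                key = parts[0].lower()
                if key not in _KEYWORDS:
                    raise ValueError(
                        f"unknown keyword {parts[0]!r}; valid keywords: "
                        + ", ".join(sorted(_KEYWORDS)))
                if len(parts) < 2:
                    raise ValueError(f"keyword {parts[0]!r} needs a value")
                values[key] = _KEYWORDS[key](parts[1].strip())
    for key, val in overrides.items():
        if val is not None:
            values[key.lower().replace("_", "")] = val
    kwargs = {}
    mapping = {"hamiltonian": "hamiltonian", "screeningr": "screening_r",
               "ccut": "c_cut", "scftole": "tol_energy",
               "scftolp": "tol_density", "maxiter": "max_iter",
               "charge": "charge"}
    for key, attr in mapping.items():
        if key in values:
            kwargs[attr] = values[key]
    if "gridshape" in values:
        shape = tuple(int(x) for x in re.split(r"[,\s]+",
                                               str(values["gridshape"]))
                      if x)
        if len(shape) == 1:
            shape = shape * 3
        kwargs["grid_shape"] = shape
    return RunConfig(**kwargs)


# --------------------------------------------------------------------------
# saved wavefunction state (simple documented container)
# --------------------------------------------------------------------------

def save_state(path, state, cell: Cell, hamiltonian: str):
    """Persist an SCF state + structure as a plain ``.npz`` array container."""
    np.savez(path,
             density=state.density, mo_coeff=state.mo_coeff,
             orbital_energies=state.orbital_energies,
             energies=np.array([state.e_electronic, state.e_core_core,
                                state.e_total, state.heat_formation]),
             n_electrons=state.n_electrons,
             converged=int(state.converged),
             symbols=np.array(cell.symbols),
             positions=cell.positions, lattice=cell.lattice,
             charge=cell.charge,
             hamiltonian=np.array(hamiltonian))


def load_state(path):
    """Load ``(state, cell, hamiltonian)`` written by :func:`save_state`."""
    from .scf import SCFState
    dat = np.load(path, allow_pickle=False)
    state = SCFState(
        density=dat["density"], mo_coeff=dat["mo_coeff"],
        orbital_energies=dat["orbital_energies"],
        e_electronic=float(dat["energies"][0]),
        e_core_core=float(dat["energies"][1]),
        e_total=float(dat["energies"][2]),
        heat_formation=float(dat["energies"][3]),
        n_electrons=int(dat["n_electrons"]),
        converged=bool(dat["converged"]))
    cell = Cell(tuple(str(s) for s in dat["symbols"]), dat["positions"],
                dat["lattice"], int(dat["charge"]))
    return state, cell, str(dat["hamiltonian"])


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def format_report(state, cell: Cell, hamiltonian: str, charges) -> str:
    """Deterministic run report (no timestamps in numeric sections)."""
    lines = [
        f"hamiltonian            {hamiltonian}",
        f"atoms                  {cell.natoms}",
        f"periodic dimensions    {cell.ndim}",
        f"valence electrons      {state.n_electrons}",
        f"converged              {state.converged}",
        f"iterations             {len(state.history)}",
        f"electronic energy (eV) {state.e_electronic:.6f}",
        f"core-core energy (eV)  {state.e_core_core:.6f}",
        f"total energy (eV)      {state.e_total:.6f}",
        f"heat of formation      {state.heat_formation:.6f} kcal/mol",
        f"HOMO (eV)              {state.homo:.6f}",
    ]
    try:
        lines.append(f"LUMO (eV)              {state.lumo:.6f}")
    except ValueError:
        pass
    lines.append("")
    lines.append("atom  element  coulson charge (e)")
    for i, (sym, q) in enumerate(zip(cell.symbols, charges)):
        lines.append(f"{i:4d}  {sym:7s}  {q: .6f}")
    lines.append("")
    lines.append("orbital energies (eV):")
    eps = state.orbital_energies
    for k in range(0, eps.size, 8):
        lines.append("  " + " ".join(f"{e:10.4f}" for e in eps[k:k + 8]))
    return "\n".join(lines) + "\n"


def write_charges_tsv(path, cell: Cell, charges):
    with open(path, "w") as fh:
        fh.write("index\telement\tcharge_e\n")
        for i, (sym, q) in enumerate(zip(cell.symbols, charges)):
            fh.write(f"{i}\t{sym}\t{q:.8f}\n")
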