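"""Embedded MNDO/AM1 element parameters and structure bookkeeping.

All per-element semiempirical constants for an sp basis: orbital exponents,
one-electron energies, resonance betas, one-center two-electron integrals,
core-repulsion exponents and (for AM1) core Gaussian triples.  The tables are
transcribed from the original method literature:

* MNDO: Dewar & Thiel, J. Am. Chem. Soc. 99, 4899 (1977) and the subsequent
  element papers (F 1978; P, S, Cl 1978-1986; Zn: Dewar & Merz 1986).
* AM1: Dewar, Zoebisch, Healy & Stewart, J. Am. Chem. Soc. 107, 3902 (1985)
  and the element extensions (F, P, S, Cl; Zn: Dewar & Merz 1988).
* Sodium: an AM1-type alkali sp set (same record served under both Hamiltonian
  tags; the original MNDO/AM1 papers never parametrized Na).  Sodium energetics
  should be treated as qualitative; it is included so that rocksalt test
  lattices are self-contained.

Derived quantities are *computed*, not transcribed:

* the Klopman monopole constant ``G`` is the one-center Coulomb integral
  ``g_ss`` expressed in hartree, and the monopole additive radius is
  ``rho0 = 1/(2G)`` (bohr);
* the charge-separation distances ``D1``/``D2`` follow from the Slater
  exponents and principal quantum number (Dewar-Thiel multipole model);
* the dipole/quadrupole additive radii ``rho1``/``rho2`` are solved from the
  one-center limits ``h_sp`` and ``(g_pp - g_p2)/2``;
* the isolated-atom electronic energy ``E_isol`` is assembled from the
  one-center terms and the atomic ground-state occupation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import EV_PER_HARTREE

MNDO = "MNDO"
AM1 = "AM1"
HAMILTONIANS = (MNDO, AM1)

#: experimental atomic heats of formation, kcal/mol
_EHEAT = {
    "H": 52.102, "C": 170.89, "N": 113.00, "O": 59.559, "F": 18.89,
    "Na": 25.85, "P": 75.57, "S": 66.40, "Cl": 28.99, "Zn": 31.17,
}

#: valence electrons
_ZVAL = {"H": 1, "C": 4, "N": 5, "O": 6, "F": 7,
         "Na": 1, "P": 5, "S": 6, "Cl": 7, "Zn": 2}

#: principal quantum number of the valence shell
_NQUANT = {"H": 1, "C": 2, "N": 2, "O": 2, "F": 2,
           "Na": 3, "P": 3, "S": 3, "Cl": 3, "Zn": 4}

#: valence occupation (n_s, n_p) of the atomic ground state
_OCC = {"H": (1, 0), "C": (2, 2), "N": (2, 3), "O": (2, 4), "F": (2, 5),
        "Na": (1, 0), "P": (2, 3), "S": (2, 4), "Cl": (2, 5), "Zn": (2, 0)}

# raw parameter tables: per hamiltonian, per element:
# uss upp zs zp betas betap alpha gss gsp gpp gp2 hsp  (eV / bohr^-1 / A^-1)
# AM1 additionally: gauss_k (eV*A), gauss_l (A^-2), gauss_m (A)

_MNDO_RAW = {
    "H": dict(uss=-11.906276, upp=0.0, zs=1.331967, zp=0.0,
              betas=-6.989064, betap=0.0, alpha=2.544134,
              gss=12.848, gsp=0.0, gpp=0.0, gp2=0.0, hsp=0.0),
    "C": dict(uss=-52.279745, upp=-39.205558, zs=1.787537, zp=1.787537,
              betas=-18.985044, betap=-7.934122, alpha=2.546380,
              gss=12.23, gsp=11.47, gpp=11.08, gp2=9.84, hsp=2.43),
    "N": dict(uss=-71.932122, upp=-57.172319, zs=2.255614, zp=2.255614,
              betas=-20.495758, betap=-20.495758, alpha=2.861342,
              gss=13.59, gsp=12.66, gpp=12.98, gp2=11.59, hsp=3.14),
    "O": dict(uss=-99.643090, upp=-77.797472, zs=2.699905, zp=2.699905,
              betas=-32.688082, betap=-32.688082, alpha=3.160604,
              gss=15.42, gsp=14.48, gpp=14.52, gp2=12.98, hsp=3.94),
    "F": dict(uss=-131.071548, upp=-105.782137, zs=2.848487, zp=2.848487,
              betas=-48.290466, betap=-36.508540, alpha=3.419661,
              gss=16.92, gsp=17.25, gpp=16.71, gp2=14.91, hsp=4.83),
    "P": dict(uss=-56.143360, upp=-42.851080, zs=2.108720, zp=1.785810,
              betas=-6.791600, betap=-6.791600, alpha=2.415280,
              gss=11.56, gsp=10.08, gpp=8.64, gp2=7.68, hsp=1.92),
    "S": dict(uss=-72.242281, upp=-56.973207, zs=2.312962, zp=2.009146,
              betas=-10.761670, betap=-10.108433, alpha=2.478026,
              gss=12.88, gsp=11.26, gpp=9.90, gp2=8.83, hsp=2.26),
    "Cl": dict(uss=-100.227166, upp=-77.378667, zs=3.784645, zp=2.036263,
               betas=-14.262320, betap=-14.262320, alpha=2.542201,
               gss=15.03, gsp=13.16, gpp=11.30, gp2=9.97, hsp=2.42),
    "Zn": dict(uss=-20.838371, upp=-19.625075, zs=2.047359, zp=1.460946,
               betas=-1.000000, betap=-2.000000, alpha=1.506457,
               gss=11.80, gsp=11.182018, gpp=13.30, gp2=12.930520,
               hsp=0.484606),
}

_AM1_RAW = {
    "H": dict(uss=-11.396427, upp=0.0, zs=1.188078, zp=0.0,
              betas=-6.173787, betap=0.0, alpha=2.882324,
              gss=12.848, gsp=0.0, gpp=0.0, gp2=0.0, hsp=0.0,
              gauss_k=(0.122796, 0.005090, -0.018336),
              gauss_l=(5.00, 5.00, 2.00),
              gauss_m=(1.20, 1.80, 2.10)),
    "C": dict(uss=-52.028658, upp=-39.614239, zs=1.808665, zp=1.685116,
              betas=-15.715783, betap=-7.719283, alpha=2.648274,
              gss=12.23, gsp=11.47, gpp=11.08, gp2=9.84, hsp=2.43,
              gauss_k=(0.011355, 0.045924, -0.020061, -0.001260),
              gauss_l=(5.00, 5.00, 5.00, 5.00),
              gauss_m=(1.60, 1.85, 2.05, 2.65)),
    "N": dict(uss=-71.860000, upp=-57.167581, zs=2.315410, zp=2.157940,
              betas=-20.299110, betap=-18.238666, alpha=2.947286,
              gss=13.59, gsp=12.66, gpp=12.98, gp2=11.59, hsp=3.14,
              gauss_k=(0.025251, 0.028953, -0.005806),
              gauss_l=(5.00, 5.00, 2.00),
              gauss_m=(1.50, 2.10, 2.40)),
    "O": dict(uss=-97.830000, upp=-78.262380, zs=3.108032, zp=2.524039,
              betas=-29.272773, betap=-29.272773, alpha=4.455371,
              gss=15.42, gsp=14.48, gpp=14.52, gp2=12.98, hsp=3.94,
              gauss_k=(0.280962, 0.081430),
              gauss_l=(5.00, 7.00),
              gauss_m=(0.847918, 1.445071)),
    "F": dict(uss=-136.105579, upp=-104.889885, zs=3.770082, zp=2.494670,
              betas=-69.590277, betap=-27.922360, alpha=5.517800,
              gss=16.92, gsp=17.25, gpp=16.71, gp2=14.91, hsp=4.83,
              gauss_k=(0.242079, 0.003607),
              gauss_l=(4.80, 4.60),
              gauss_m=(0.930, 1.660)),
    "P": dict(uss=-42.029863, upp=-34.030709, zs=1.981280, zp=1.875150,
              betas=-6.353764, betap=-6.590709, alpha=2.455322,
              gss=11.560005, gsp=5.237449, gpp=7.877589, gp2=7.307648,
              hsp=0.779238,
              gauss_k=(-0.031827, 0.018470, 0.033290),
              gauss_l=(6.00, 7.00, 9.00),
              gauss_m=(1.474323, 1.779354, 3.006576)),
    "S": dict(uss=-56.694056, upp=-48.717049, zs=2.366515, zp=1.667263,
              betas=-3.920566, betap=-7.905278, alpha=2.461648,
              gss=11.786329, gsp=8.663127, gpp=10.039308, gp2=7.781688,
              hsp=2.532137,
              gauss_k=(-0.509195, -0.011863, 0.012334),
              gauss_l=(4.593691, 5.865731, 13.557336),
              gauss_m=(0.770665, 1.503313, 2.009173)),
    "Cl": dict(uss=-111.613948, upp=-76.640107, zs=3.631376, zp=2.076799,
               betas=-24.594670, betap=-14.637216, alpha=2.919368,
               gss=15.03, gsp=13.16, gpp=11.30, gp2=9.97, hsp=2.42,
               gauss_k=(0.094243, 0.027168),
               gauss_l=(4.00, 4.00),
               gauss_m=(1.30, 2.10)),
    "Zn": dict(uss=-21.040008, upp=-17.655574, zs=1.954299, zp=1.372365,
               betas=-1.997429, betap=-4.758119, alpha=1.484563,
               gss=11.80, gsp=11.182018, gpp=13.30, gp2=12.930520,
               hsp=0.484606),
}

# AM1-type alkali sp set for sodium, served under both Hamiltonian tags.
_NA_RAW = dict(uss=-5.255536, upp=-2.081278, zs=0.679779, zp=0.980284,
               betas=-1.453694, betap=-0.229806, alpha=2.248716,
               gss=7.345676, gsp=6.541020, gpp=4.301023, gp2=3.845585,
               hsp=0.531272)
_MNDO_RAW["Na"] = dict(_NA_RAW)
_AM1_RAW["Na"] = dict(_NA_RAW)

SUPPORTED_ELEMENTS = tuple(sorted(_EHEAT, key=lambda s: _ZVAL[s]))


class UnsupportedSpeciesError(ValueError):
    """Element/Hamiltonian combination not covered by the embedded tables."""


@dataclass(frozen=True)
class ElementParams:
    """Full semiempirical parameter record for one element and Hamiltonian.

    Energies in eV, Slater exponents in bohr^-1, the core-repulsion exponent
    ``alpha`` in Å^-1, multipole lengths (``d1``, ``d2``, ``rho0..rho2``) in
    bohr, the monopole constant ``g_monopole`` in hartree.
    """

    symbol: str
    hamiltonian: str
    z_valence: int
    n_principal: int
    uss: float
    upp: float
    zeta_s: float
    zeta_p: float
    beta_s: float
    beta_p: float
    alpha: float
    gss: float
    gsp: float
    gpp: float
    gp2: float
    hsp: float
    eheat: float
    eisol: float
    g_monopole: float
    rho0: float
    rho1: float
    rho2: float
    d1: float
    d2: float
    gauss_k: tuple = field(default=())
    gauss_l: tuple = field(default=())
    gauss_m: tuple = field(default=())

    @property
    def nbasis(self) -> int:
        """Basis size: 1 for an s-only atom (H), 4 for sp atoms."""
        return 1 if self.zeta_p == 0.0 else 4

    @property
    def hpp(self) -> float:
        """One-center p-p' exchange integral, (g_pp - g_p2)/2, eV."""
        return 0.5 * (self.gpp - self.gp2)


def _slater_norm(n: int, zeta: float) -> float:
    return (2.0 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


def _charge_separations(n: int, zs: float, zp: float) -> tuple[float, float]:
    """Dewar-Thiel charge separations D1 (sp dipole) and D2 (pp quadrupole)."""
    ns, np_ = _slater_norm(n, zs), _slater_norm(n, zp)
    d1 = ns * np_ * math.factorial(2 * n + 1) \
        / ((zs + zp) ** (2 * n + 2) * math.sqrt(3.0))
    d2 = math.sqrt((2 * n + 1) * (2 * n + 2) / 20.0) / zp
    return d1, d2


def _dipole_self_energy(rho: float, d1: float) -> float:
    # one-center limit of the [sp,sp] dipole-dipole Klopman interaction, a.u.
    return 0.25 * (1.0 / rho - 1.0 / math.sqrt(d1 * d1 + rho * rho))


def _quadrupole_self_energy(rho: float, d2: float) -> float:
    # one-center limit of the square-quadrupole [pp',pp'] self-interaction,
    # a.u. (the classical determination of the quadrupole additive radius;
    # validated against published MNDO/AM1 molecular heats of formation)
    return (0.125 / rho
            - 0.25 / math.sqrt(d2 * d2 + rho * rho)
            + 0.125 / math.sqrt(2.0 * d2 * d2 + rho * rho))


def _solve_additive_radius(target_au: float, self_energy, dist: float) -> float:
    f = lambda rho: self_energy(rho, dist) - target_au
    return brentq(f, 1e-4, 100.0, xtol=1e-14, rtol=1e-15)


def _isolated_atom_energy(raw: dict, occ: tuple[int, int]) -> float:
    """Electronic energy of the neutral atom in its ground configuration, eV.

    Hund filling of the valence shell; the pair couplings follow the standard
    one-center NDDO energy expressions (verified against the published E_isol
    tables for C, N, O, F, P, S, Cl, Zn).
    """
    ns, np_ = occ
    uss, upp = raw["uss"], raw["upp"]
    gss, gsp, gpp, gp2, hsp = (raw["gss"], raw["gsp"], raw["gpp"],
                               raw["gp2"], raw["hsp"])
    hpp = 0.5 * (gpp - gp2)
    e = ns * uss + np_ * upp
    if ns == 2:
        e += gss
    # s-p Coulomb and (parallel-spin) exchange
    e += ns * np_ * gsp
    if ns == 2:
        e -= np_ * hsp
    # p-p couplings under Hund filling
    ndouble = max(0, np_ - 3)
    nsingle = np_ - 2 * ndouble
    e += ndouble * gpp
    e += (ndouble * (ndouble - 1) // 2) * (4.0 * gp2 - 2.0 * hpp)
    e += ndouble * nsingle * (2.0 * gp2 - hpp)
    e += (nsingle * (nsingle - 1) // 2) * (gp2 - hpp)
    return e


def _build(symbol: str, hamiltonian: str) -> ElementParams:
    raw = (_MNDO_RAW if hamiltonian == MNDO else _AM1_RAW)[symbol]
    n = _NQUANT[symbol]
    g = raw["gss"] / EV_PER_HARTREE
    rho0 = 1.0 / (2.0 * g)
    if raw["zp"] == 0.0:
        d1 = d2 = rho1 = rho2 = 0.0
    else:
        d1, d2 = _charge_separations(n, raw["zs"], raw["zp"])
        rho1 = _solve_additive_radius(raw["hsp"] / EV_PER_HARTREE,
                                      _dipole_self_energy, d1)
        rho2 = _solve_additive_radius(
            0.5 * (raw["gpp"] - raw["gp2"]) / EV_PER_HARTREE,
            _quadrupole_self_energy, d2)
    return ElementParams(
        symbol=symbol, hamiltonian=hamiltonian,
        z_valence=_ZVAL[symbol], n_principal=n,
        uss=raw["uss"], upp=raw["upp"],
        zeta_s=raw["zs"], zeta_p=raw["zp"],
        beta_s=raw["betas"], beta_p=raw["betap"], alpha=raw["alpha"],
        gss=raw["gss"], gsp=raw["gsp"], gpp=raw["gpp"], gp2=raw["gp2"],
        hsp=raw["hsp"],
        eheat=_EHEAT[symbol],
        eisol=_isolated_atom_energy(raw, _OCC[symbol]),
        g_monopole=g, rho0=rho0, rho1=rho1, rho2=rho2, d1=d1, d2=d2,
        gauss_k=tuple(raw.get("gauss_k", ())),
        gauss_l=tuple(raw.get("gauss_l", ())),
        gauss_m=tuple(raw.get("gauss_m", ())),
    )


_CACHE: dict[tuple[str, str], ElementParams] = {}


def get_element_params(symbol: str, hamiltonian: str = AM1) -> ElementParams:
    """Return the immutable parameter record for ``symbol``/``hamiltonian``."""
    sym = symbol.strip().capitalize()
    ham = hamiltonian.strip().upper()
    if sym not in _EHEAT or ham not in HAMILTONIANS:
        raise UnsupportedSpeciesError(
            f"unsupported species: element {symbol!r} with "
            f"hamiltonian {hamiltonian!r} (supported elements: "
            f"{', '.join(SUPPORTED_ELEMENTS)}; hamiltonians: MNDO, AM1)")
    key = (sym, ham)
    if key not in _CACHE:
        _CACHE[key] = _build(sym, ham)
    return _CACHE[key]


def derived_multipole_distances(params: ElementParams) -> tuple[float, float]:
    """Charge-separation distances (D1, D2) in bohr for an sp element."""
    if params.nbasis == 1:
        raise ValueError(
            f"no multipoles for s-only basis (element {params.symbol})")
    return params.d1, params.d2


def valence_electron_count(cell, hamiltonian: str = AM1) -> int:
    """Number of valence electrons of the structure (minus net charge)."""
    total = sum(get_element_params(s, hamiltonian).z_valence
                for s in cell.symbols)
    return total - cell.charge


def orbital_count(cell) -> int:
    """Size of the valence sp basis: 1 orbital for H, 4 for other elements."""
    return sum(get_element_params(s, AM1).nbasis for s in cell.symbols)


def parameter_table(hamiltonian: str = AM1) -> str:
    """Tab-separated dump of the full parameter table (for inspection)."""
    cols = ["symbol", "z_valence", "n_principal", "uss", "upp", "zeta_s",
            "zeta_p", "beta_s", "beta_p", "alpha", "gss", "gsp", "gpp",
            "gp2", "hsp", "eheat", "eisol", "g_monopole", "rho0", "rho1",
            "rho2", "d1", "d2"]
    lines = ["\t".join(cols)]
    for sym in SUPPORTED_ELEMENTS:
        p = get_element_params(sym, hamiltonian)
        row = [str(getattr(p, c)) if c in ("symbol",)
               else f"{getattr(p, c):.6f}" if isinstance(getattr(p, c), float)
               else str(getattr(p, c)) for c in cols]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
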