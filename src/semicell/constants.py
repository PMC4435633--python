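"""Physical constants and unit conversions.

The legacy MNDO-era conversion factors are used deliberately: the semiempirical
parameter sets embedded in :mod:`semicell.parameters` were calibrated against
programs that used exactly these rounded values, and reproducing published
heats of formation to 0.1 kcal/mol requires keeping them.
"""

#: bohr radius in Å (legacy rounded value used by the original MNDO programs)
BOHR_ANGSTROM = 0.529167

#: hartree in eV (legacy rounded value)
EV_PER_HARTREE = 27.21

#: eV in kcal/mol (legacy rounded value)
KCAL_PER_EV = 23.061

#: hartree in kcal/mol
KCAL_PER_HARTREE = EV_PER_HARTREE * KCAL_PER_EV

#: e*bohr in Debye
DEBYE_PER_E_BOHR = 2.541462


def angstrom_to_bohr(x):
    return x / BOHR_ANGSTROM


def bohr_to_angstrom(x):
    return x * BOHR_ANGSTROM
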