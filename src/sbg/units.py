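"""Physical constants and unit conversions.

All internal computation is carried out in Hartree atomic units with
mass-weighted Cartesian coordinates measured in sqrt(m_e)*bohr, so that
hbar = 1 and the vibrational kinetic operator is -1/2 * Laplacian.
I/O uses the conventional Angstrom / amu / cm^-1 units.
"""

# CODATA-consistent conversion factors
AMU_TO_ME = 1822.888486          # atomic mass unit -> electron masses
ANGSTROM_TO_BOHR = 1.8897261255  # Angstrom -> bohr
HARTREE_TO_CM = 219474.6313705   # hartree -> cm^-1


def wavenumber_to_hartree(cm1: float) -> float:
    return cm1 / HARTREE_TO_CM


def hartree_to_wavenumber(e: float) -> float:
    return e * HARTREE_TO_CM
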