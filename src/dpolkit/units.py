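"""Unit conventions and physical constants.

All internal quantities are Hartree atomic units: length in bohr, charge in
elementary charges, potential in hartree/e, field in hartree/(e·bohr),
dipole in e·bohr, polarizability in bohr³.  Conversions to the field's
customary I/O units (Å, Debye, Å³, g/mL) happen only at the boundaries.
"""

# CODATA length / dipole conversions
BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
DEBYE_PER_AU = 2.541746473  # 1 e·bohr in Debye

# Boltzmann constant in hartree per kelvin
KB_HARTREE_PER_K = 3.166811563e-6

# Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

# 1 bohr³ in mL (cm³); derived from the length conversion for consistency
BOHR_RADIUS_CM = 1e-8 / BOHR_PER_ANGSTROM
ML_PER_BOHR3 = BOHR_RADIUS_CM**3

# volumes
BOHR3_PER_NM3 = (10.0 * BOHR_PER_ANGSTROM) ** 3
BOHR3_PER_ANGSTROM3 = BOHR_PER_ANGSTROM**3


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def au_to_debye(mu):
    return mu * DEBYE_PER_AU


def debye_to_au(mu):
    return mu / DEBYE_PER_AU


def bohr3_to_angstrom3(a):
    return a / BOHR3_PER_ANGSTROM3


def angstrom3_to_bohr3(a):
    return a * BOHR3_PER_ANGSTROM3
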