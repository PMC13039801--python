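"""Unit system and physical constants.

File formats carry coordinates in Å and energies in Hartree.  Molecular
dynamics runs internally in Å / fs / amu, so energies and forces are
converted once at the MD boundary.  All conversion factors live here and
nowhere else.
"""

# Length
ANGSTROM_PER_BOHR = 0.529177210903  # CODATA 2018
BOHR_PER_ANGSTROM = 1.8897259886

# Energy
KCALMOL_PER_HARTREE = 627.509474
KJMOL_PER_KCALMOL = 4.184

# 1 amu·Å²/fs² expressed in kJ/mol:
#   1.66053906660e-27 kg · (1e-10 m / 1e-15 s)² · 6.02214076e23 / 1000
_AMU_KG = 1.66053906660e-27
_AVOGADRO = 6.02214076e23
KJMOL_PER_MDUNIT = _AMU_KG * 1.0e10 * _AVOGADRO / 1000.0  # ≈ 1e4

# MD internal energy unit (amu·Å²/fs²) per Hartree
MDUNIT_PER_HARTREE = KCALMOL_PER_HARTREE * KJMOL_PER_KCALMOL / KJMOL_PER_MDUNIT

# Boltzmann constant
KB_HARTREE_PER_K = 3.166811563e-6
KB_MDUNIT_PER_K = KB_HARTREE_PER_K * MDUNIT_PER_HARTREE


def hartree_per_angstrom_to_hartree_per_bohr(g):
    """Convert a gradient/force from Ha/Å to Ha/Bohr."""
    return g / BOHR_PER_ANGSTROM


def hartree_per_bohr_to_hartree_per_angstrom(g):
    return g * BOHR_PER_ANGSTROM
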