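"""Physical constants and unit conversions.

Conventions used throughout the package:

* geometry I/O and internal Cartesian coordinates: Angstrom
* energies: kcal/mol, forces: kcal/mol/Angstrom (declared per dataset)
* electrostatic-potential descriptor, charges and dipoles: atomic units
  (e, Bohr, Hartree)
* time: fs, masses: amu, temperature: K

All conversions live here so that no module hard-codes a constant.
"""

from __future__ import annotations

# CODATA-2018 values
BOHR_PER_ANGSTROM: float = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR: float = 0.529177210903
KCALMOL_PER_HARTREE: float = 627.509474063

#: Boltzmann constant in kcal/mol/K
KB_KCALMOL: float = 0.001987204259

#: 1 kcal/mol/(amu * Angstrom) expressed as acceleration in Angstrom/fs^2
ACC_KCALMOL: float = 4.184e-4

#: speed of light in cm/fs (converts 1/fs frequencies to wavenumbers)
C_CM_PER_FS: float = 2.99792458e-5

#: Bondi van-der-Waals radii, Angstrom (overridable wherever they are used)
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
}

#: standard atomic masses, amu
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00794,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
}
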