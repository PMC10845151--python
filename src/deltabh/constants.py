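"""Element tables and physical constants, pinned for bit-reproducibility.

All values are hard-coded literals rather than imported from a constants
library so that results do not drift with dependency upgrades.
"""

from __future__ import annotations

# Covalent radii in Angstrom (Cordero et al. 2008 single-bond values).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8}
SYMBOLS: dict[int, str] = {z: s for s, z in ATOMIC_NUMBERS.items()}

# Standard atomic weights (amu), CODATA/IUPAC 2021 abridged.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}

# Maximum valence used by the synthetic generator.
VALENCES: dict[str, int] = {"H": 1, "C": 4, "N": 3, "O": 2}

# Physical constants (CODATA 2018).
PLANCK_H = 6.62607015e-34        # J s
SPEED_OF_LIGHT = 2.99792458e10   # cm/s
BOLTZMANN_K = 1.380649e-23       # J/K
AVOGADRO_NA = 6.02214076e23      # 1/mol
AMU_KG = 1.66053906660e-27       # kg
ATM_PA = 101325.0                # Pa
CAL_J = 4.184                    # J per thermochemical calorie

# Gas constant in kcal/(mol K) and cal/(mol K).
R_KCAL = BOLTZMANN_K * AVOGADRO_NA / (CAL_J * 1000.0)
R_CAL = R_KCAL * 1000.0

# Pinned wavenumber-to-energy conversion: 1 cm^-1 in kcal/mol.
CM1_TO_KCAL = 2.85914e-3

# Default bond-detection scale applied to the sum of covalent radii.
DEFAULT_BOND_SCALE = 1.2
# Minimum physically sensible interatomic distance (Angstrom).
MIN_ATOM_DISTANCE = 0.5

# Spectral-fingerprint comparison tolerances.
CONNECTIVITY_TOL = 1e-4
CONFORMATION_TOL = 1e-3
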