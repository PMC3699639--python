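"""Unit conversions and physical constants.

The electronic-structure conversions (hartree->eV, bohr->angstrom,
eV->kcal/mol) deliberately use the historical values that the MNDO/AM1/PM3
parameterizations were fitted with; swapping in modern CODATA values shifts
heats of formation by a few hundredths of a kcal/mol and breaks agreement
with the published reference numbers.
"""

# Method-defining conversion constants (MNDO-era).
EV = 27.21  # eV per hartree
A0 = 0.529167  # angstrom per bohr
EVKCAL = 23.061  # kcal/mol per eV

HARTREE_KCAL = EV * EVKCAL  # kcal/mol per hartree

ANGSTROM_TO_BOHR = 1.0 / A0
BOHR_TO_ANGSTROM = A0

# Atomic masses (amu), standard atomic weights.
MASSES = {"H": 1.00794, "C": 12.011, "N": 14.007, "O": 15.999}

# Bondi van der Waals radii (angstrom).
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52}

# Frequency conversion: sqrt(eigenvalue of mass-weighted Hessian in
# eV / (bohr^2 amu)) -> cm^-1.  Derived from SI constants.
import scipy.constants as _c

_EV_J = _c.electron_volt
_BOHR_M = A0 * 1e-10
_AMU_KG = _c.atomic_mass

# omega[rad/s] = sqrt(lam * EV_J / (AMU_KG * BOHR_M**2)); nu_tilde = omega/(2 pi c)
FREQ_AU_TO_CM1 = (
    (_EV_J / (_AMU_KG * _BOHR_M**2)) ** 0.5 / (2.0 * 3.141592653589793 * _c.c * 100.0)
)
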