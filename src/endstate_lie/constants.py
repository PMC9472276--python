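"""Physical constants and unit conversions.

A single internal energy unit (eV) is used everywhere inside the package;
free energies are reported in kcal/mol, the unit experimental binding data
is tabulated in.
"""

# 1 eV = 23.060548 kcal/mol (CODATA-derived; fixed here once so that every
# module converts identically).
EV_TO_KCALMOL: float = 23.060548

# 1 Hartree in eV, for backends that natively report atomic units.
HARTREE_TO_EV: float = 27.211386245988

# Coulomb constant in eV * Angstrom / e^2.
COULOMB_EV_ANGSTROM: float = 14.399645

# Gas constant in kcal / (mol K), used for dG = RT ln(Ki).
R_KCAL_PER_MOL_K: float = 1.987204e-3

# Default temperature for converting IC50/Ki to a free energy.
DEFAULT_TEMPERATURE_K: float = 298.15


def ev_to_kcalmol(x: float) -> float:
    """Convert an energy from eV to kcal/mol."""
    return x * EV_TO_KCALMOL


def kcalmol_to_ev(x: float) -> float:
    """Convert an energy from kcal/mol to eV."""
    return x / EV_TO_KCALMOL
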