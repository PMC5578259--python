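"""Physical constants and unit conversion helpers.

All formulas in the package are evaluated in SI internally; public
interfaces use the working units of colloid science (nm, mV, e/nm2,
mg/m2, mM).  CODATA values are taken from :mod:`scipy.constants`.
"""

from __future__ import annotations

from scipy import constants as _c

#: Elementary charge [C]
E_CHARGE: float = _c.elementary_charge
#: Boltzmann constant [J/K]
K_B: float = _c.Boltzmann
#: Vacuum permittivity [F/m]
EPS0: float = _c.epsilon_0
#: Avogadro constant [1/mol]
N_A: float = _c.Avogadro

# Aqueous defaults at 298 K.  The relative permittivity of water and its
# viscosity enter every electrokinetic formula; they are not tabulated in
# the experimental descriptions this package models, so the standard
# handbook values are used and may be overridden per Medium.
WATER_REL_PERMITTIVITY: float = 78.5
WATER_VISCOSITY_PA_S: float = 0.89e-3
STANDARD_TEMPERATURE_K: float = 298.0

NM = 1e-9  # m per nm
MV = 1e-3  # V per mV


def uC_per_cm2_to_e_per_nm2(value: float) -> float:
    """Convert a surface charge density from uC/cm2 to e/nm2.

    1 uC/cm2 = 1e-6 C / 1e-4 m2 = 1e-2 C/m2; dividing by e and scaling
    to nm2 gives the exact linear factor used here (its own inverse
    round-trips to machine precision).
    """
    return value * 1e-2 / E_CHARGE * NM**2


def e_per_nm2_to_uC_per_cm2(value: float) -> float:
    """Inverse of :func:`uC_per_cm2_to_e_per_nm2`."""
    return value * E_CHARGE / NM**2 / 1e-2


def e_per_nm2_to_C_per_m2(value: float) -> float:
    return value * E_CHARGE / NM**2


def C_per_m2_to_e_per_nm2(value: float) -> float:
    return value * NM**2 / E_CHARGE
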