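"""Solution physical chemistry: media, buffers, screening lengths, ion drag.

The electrokinetic and condensation formulas downstream all feed on three
quantities computed here from the buffer composition: the ionic strength I,
the Debye parameter kappa = 1/lambda_D, and the Bjerrum length lambda_B.
Multivalent ions contribute fully to I and kappa, but the mobility and
charge formulas elsewhere always assume monovalent counterions (z = 1),
mirroring the low-ionic-strength buffers these models were built for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .constants import (
    EPS0,
    E_CHARGE,
    K_B,
    N_A,
    NM,
    STANDARD_TEMPERATURE_K,
    WATER_REL_PERMITTIVITY,
    WATER_VISCOSITY_PA_S,
    e_per_nm2_to_uC_per_cm2,
    uC_per_cm2_to_e_per_nm2,
)

__all__ = [
    "Medium",
    "IonSpecies",
    "BufferSolution",
    "bjerrum_length",
    "ionic_strength",
    "debye_parameter",
    "debye_length",
    "convert_charge_density",
    "drag_coefficient",
    "LIMITING_CONDUCTIVITY",
    "default_buffer",
    "DEFAULT_BUFFER_TABLE",
]


class ValidationError(ValueError):
    """Raised when a physical object violates its invariants."""


@dataclass(frozen=True)
class Medium:
    """Continuum solvent: temperature [K], relative permittivity, viscosity [Pa s]."""

    temperature: float = STANDARD_TEMPERATURE_K
    relative_permittivity: float = WATER_REL_PERMITTIVITY
    viscosity: float = WATER_VISCOSITY_PA_S

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.relative_permittivity > 1):
            raise ValidationError(
                f"relative permittivity must exceed 1, got {self.relative_permittivity}"
            )
        if not (self.viscosity > 0):
            raise ValidationError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species of a buffer.

    concentration is in mol/m3, numerically identical to mM.
    limiting_molar_conductivity (Lambda0) is in S m2/mol and is only
    required when the species feeds an ionic drag coefficient.
    """

    name: str
    valence: int
    concentration: float
    limiting_molar_conductivity: float | None = None

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValidationError(f"ion {self.name!r}: valence must be nonzero")
        if self.concentration < 0:
            raise ValidationError(f"ion {self.name!r}: concentration must be >= 0")


@dataclass(frozen=True)
class BufferSolution:
    """An electroneutral buffered electrolyte at a given pH."""

    pH: float
    ions: tuple[IonSpecies, ...]
    medium: Medium = field(default_factory=Medium)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ValidationError(f"pH must lie in [0, 14], got {self.pH}")
        object.__setattr__(self, "ions", tuple(self.ions))
        net = sum(i.valence * i.concentration for i in self.ions)
        scale = sum(abs(i.valence) * i.concentration for i in self.ions)
        if scale > 0 and abs(net) > 1e-9 * scale:
            raise ValidationError(
                f"buffer is not electroneutral: sum(z*c) = {net:g} mol/m3"
            )


def bjerrum_length(medium: Medium) -> float:
    """Bjerrum length lambda_B = e^2 / (4 pi eps0 epsr kB T), in nm.

    The distance at which two unit charges interact with thermal energy;
    about 0.71 nm in water at 298 K.
    """
    lb = E_CHARGE**2 / (
        4.0
        * math.pi
        * EPS0
        * medium.relative_permittivity
        * K_B
        * medium.temperature
    )
    return lb / NM


def ionic_strength(buffer: BufferSolution) -> float:
    """Ionic strength I = (1/2) sum c_i z_i^2, in mol/m3 (== mM)."""
    if not buffer.ions:
        raise ValidationError("buffer has no ions; ionic strength undefined")
    return 0.5 * sum(i.concentration * i.valence**2 for i in buffer.ions)


def debye_parameter(buffer: BufferSolution) -> float:
    """Inverse Debye screening length kappa, in 1/nm.

    kappa^2 = 2 NA e^2 I / (eps0 epsr kB T), with I in mol/m3 so the
    Avogadro factor turns moles into number density.  Scales as sqrt(I).
    """
    I = ionic_strength(buffer)
    if I <= 0:
        raise ValidationError("ionic strength must be > 0 for a finite Debye length")
    med = buffer.medium
    kappa_sq = (
        2.0
        * N_A
        * E_CHARGE**2
        * I
        / (EPS0 * med.relative_permittivity * K_B * med.temperature)
    )
    return math.sqrt(kappa_sq) * NM


def debye_length(buffer: BufferSolution) -> float:
    """Debye screening length 1/kappa in nm."""
    return 1.0 / debye_parameter(buffer)


def convert_charge_density(value: float, to: str = "e_per_nm2") -> float:
    """Convert a surface charge density between uC/cm2 and e/nm2.

    ``to="e_per_nm2"`` interprets ``value`` as uC/cm2; ``to="uC_per_cm2"``
    interprets it as e/nm2.  Exact linear map through the elementary
    charge; round-trips to machine precision.
    """
    if not math.isfinite(value):
        raise ValidationError("charge density must be finite")
    if to == "e_per_nm2":
        return uC_per_cm2_to_e_per_nm2(value)
    if to == "uC_per_cm2":
        return e_per_nm2_to_uC_per_cm2(value)
    raise ValueError(f"unknown target unit {to!r}")


#: Limiting molar conductivities Lambda0 at 298 K in water [S m2/mol]
#: (standard tabulated values; per-ion override via IonSpecies).
LIMITING_CONDUCTIVITY: dict[str, float] = {
    "H+": 349.8e-4,
    "OH-": 198.0e-4,
    "Na+": 50.1e-4,
    "K+": 73.5e-4,
    "Cl-": 76.3e-4,
    "Acetate-": 40.9e-4,
    "H2PO4-": 36.0e-4,
    "HPO4-2": 114.0e-4,
    "B(OH)4-": 35.0e-4,
    "BisTrisH+": 25.0e-4,
    "SO4-2": 160.0e-4,
}


def drag_coefficient(ion: IonSpecies, medium: Medium | None = None) -> float:
    """Dimensionless ionic drag coefficient m of the Ohshima mobility formula.

    m = 2 epsr eps0 kB T NA / (3 eta Lambda0), with Lambda0 the limiting
    molar conductivity of the species.  For K+ in water at 298 K this is
    about 0.18.  Slow ions (small Lambda0) drag more.
    """
    medium = medium or Medium()
    lam0 = ion.limiting_molar_conductivity
    if lam0 is None:
        lam0 = LIMITING_CONDUCTIVITY.get(ion.name)
    if lam0 is None or lam0 <= 0:
        raise ValidationError(
            f"ion {ion.name!r} has no limiting molar conductivity; provide one "
            "or use a name present in LIMITING_CONDUCTIVITY"
        )
    return (
        2.0
        * medium.relative_permittivity
        * EPS0
        * K_B
        * medium.temperature
        * N_A
        / (3.0 * medium.viscosity * lam0)
    )


def _salt(pH: float, cation: str, anion: str, conc_mM: float,
          medium: Medium) -> BufferSolution:
    return BufferSolution(
        pH=pH,
        ions=(
            IonSpecies(cation, +1, conc_mM,
                       LIMITING_CONDUCTIVITY.get(cation)),
            IonSpecies(anion, -1, conc_mM,
                       LIMITING_CONDUCTIVITY.get(anion)),
        ),
        medium=medium,
    )


#: Approximate default buffer compositions (ionic strength <= ~2 mM),
#: keyed by nominal pH: acetate at pH 4-5, monosodium phosphate at
#: pH 6-7, borate at pH 8-10, dilute HCl at pH 3, and a Bis-Tris/HCl
#: alternative at pH 7.  These are editable stand-ins for typical
#: low-ionic-strength recipes, not reconstructions of any particular
#: laboratory's buffers.
def default_buffer(pH: float, medium: Medium | None = None) -> BufferSolution:
    medium = medium or Medium()
    key = int(round(pH))
    recipes: dict[int, tuple[str, str, float]] = {
        3: ("H+", "Cl-", 1.0),
        4: ("Na+", "Acetate-", 1.0),
        5: ("Na+", "Acetate-", 1.5),
        6: ("Na+", "H2PO4-", 1.5),
        7: ("Na+", "H2PO4-", 2.0),
        8: ("Na+", "B(OH)4-", 1.0),
        9: ("Na+", "B(OH)4-", 1.5),
        10: ("Na+", "B(OH)4-", 2.0),
    }
    if key not in recipes:
        raise ValidationError(f"no default buffer recipe near pH {pH}")
    cation, anion, conc = recipes[key]
    return _salt(pH, cation, anion, conc, medium)


DEFAULT_BUFFER_TABLE: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10)
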