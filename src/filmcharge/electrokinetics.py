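"""Electrokinetics of spherical colloids: Ohshima's approximate mobility,
its inversion to the zeta potential, and the electrokinetic charge density.

Mobility
--------
For a sphere of radius a in a symmetrical z:z electrolyte with reduced
zeta potential y = z e zeta / kB T, Ohshima's analytic approximation is

    mu = (2 eps0 epsr zeta / 3 eta) *
         [ f1(ka) - y^2 ( f3(ka) + (m+ + m-)/2 * f4(ka) ) ]

    f1 = 1 + 1 / (2 [1 + 2.5 / {ka (1 + 2 e^-ka)}]^3)        (Henry term)
    f3 = ka (ka + 1.3 e^(-0.18 ka) + 2.5) /
         (2 (ka + 1.2 e^(-7.4 ka) + 4.8)^3)
    f4 = 9 ka (ka + 5.2 e^(-3.9 ka) + 5.6) /
         (8 (ka - 1.55 e^(-0.32 ka) + 6.02)^3)

with m+ and m- the dimensionless drag coefficients of the counter- and
co-ion.  f1 interpolates Henry's function between the Hueckel (ka -> 0,
bracket -> 1) and Smoluchowski (ka -> inf, bracket -> 3/2) limits; the
y^2 terms are the relaxation correction, which makes mobility
non-monotonic in zeta at large ka — hence inversion returns the
smallest-|zeta| branch and annotates when a second root exists.

Charge
------
The electrokinetic charge density (the charge inside the slip plane that
actually drives electrophoresis) follows the Ohshima–Healy–White
charge–potential relationship for a sphere,

    sigma_ek = (2 eps0 epsr kappa kB T / z e) sinh(y/2) *
               sqrt(1 + (1/ka) * 2/cosh^2(y/4)
                      + (1/ka^2) * 8 ln cosh(y/4) / sinh^2(y/2)),

which reduces to flat-plate Gouy–Chapman as ka -> inf and linearizes to
the Debye–Hueckel sphere result eps0 epsr zeta (1 + ka)/a at small zeta.
Both formulas are used with z = 1: in the dilute buffers modelled here
monovalent ions dominate, and kappa is still computed from the full
ionic composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import EPS0, E_CHARGE, K_B, MV, NM, C_per_m2_to_e_per_nm2
from .physchem import BufferSolution, debye_parameter

__all__ = [
    "ColloidSpec",
    "MobilityCurve",
    "ZetaResult",
    "mobility_from_zeta",
    "zeta_from_mobility",
    "sigma_ek_from_zeta",
    "zeta_from_sigma",
    "complex_pI",
]

#: Mobility output unit: 1e-8 m2 V^-1 s^-1 (the conventional scale).
MOBILITY_UNIT = 1e-8
#: Default drag coefficients (order of the K+/Cl- values) when none given.
DEFAULT_DRAG = (0.18, 0.17)
ZETA_BRACKET_MV = 200.0


@dataclass(frozen=True)
class ColloidSpec:
    """A latex sphere: radius [nm] and bare (titratable) surface charge
    density [e/nm2]."""

    radius: float
    bare_charge_density: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"colloid radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class MobilityCurve:
    """Electrophoretic mobility [1e-8 m2/Vs] versus pH.

    ``buffers`` holds one BufferSolution per point (the buffer sets the
    screening at that pH).  ``metadata`` may carry generator ground truth.
    """

    pH: np.ndarray
    mobility: np.ndarray
    buffers: tuple[BufferSolution, ...]
    metadata: dict | None = None

    def __post_init__(self) -> None:
        ph = np.asarray(self.pH, dtype=float)
        mu = np.asarray(self.mobility, dtype=float)
        if ph.ndim != 1 or ph.shape != mu.shape or ph.size < 2:
            raise ValueError("need matching 1-D pH and mobility arrays, n >= 2")
        if np.any(np.diff(ph) <= 0):
            raise ValueError("pH grid must be strictly increasing")
        if len(self.buffers) != ph.size:
            raise ValueError("need one buffer per curve point")
        object.__setattr__(self, "pH", ph)
        object.__setattr__(self, "mobility", mu)
        object.__setattr__(self, "buffers", tuple(self.buffers))


@dataclass(frozen=True)
class ZetaResult:
    """Inverted electrokinetic state at one condition."""

    zeta: float  # mV
    sigma_ek: float  # e/nm2
    kappa_a: float
    branch_note: str = ""


def _henry_f1(ka: float) -> float:
    return 1.0 + 0.5 / (1.0 + 2.5 / (ka * (1.0 + 2.0 * math.exp(-ka)))) ** 3


def _relax_f3(ka: float) -> float:
    return (
        ka
        * (ka + 1.3 * math.exp(-0.18 * ka) + 2.5)
        / (2.0 * (ka + 1.2 * math.exp(-7.4 * ka) + 4.8) ** 3)
    )


def _relax_f4(ka: float) -> float:
    return (
        9.0
        * ka
        * (ka + 5.2 * math.exp(-3.9 * ka) + 5.6)
        / (8.0 * (ka - 1.55 * math.exp(-0.32 * ka) + 6.02) ** 3)
    )


def _kappa_a(colloid: ColloidSpec, buffer: BufferSolution) -> float:
    ka = debye_parameter(buffer) * colloid.radius
    if ka <= 0:
        raise ValueError("kappa * a must be > 0")
    return ka


def mobility_from_zeta(
    zeta: float,
    colloid: ColloidSpec,
    buffer: BufferSolution,
    drag: tuple[float, float] = DEFAULT_DRAG,
) -> float:
    """Electrophoretic mobility [1e-8 m2/Vs] from zeta [mV] (z = 1)."""
    ka = _kappa_a(colloid, buffer)
    med = buffer.medium
    zeta_v = zeta * MV
    y = E_CHARGE * zeta_v / (K_B * med.temperature)
    prefactor = 2.0 * EPS0 * med.relative_permittivity * zeta_v / (3.0 * med.viscosity)
    m_plus, m_minus = drag
    mu = prefactor * (
        _henry_f1(ka)
        - y**2 * (_relax_f3(ka) + 0.5 * (m_plus + m_minus) * _relax_f4(ka))
    )
    return mu / MOBILITY_UNIT


def zeta_from_mobility(
    mu: float,
    colloid: ColloidSpec,
    buffer: BufferSolution,
    drag: tuple[float, float] = DEFAULT_DRAG,
    bracket_mV: float = ZETA_BRACKET_MV,
    tol: float = 1e-3,
) -> ZetaResult:
    """Invert the mobility approximation for zeta, smallest-|zeta| branch.

    The relaxation correction makes mu(zeta) non-monotonic at large
    kappa*a, so up to two roots can exist inside the bracket; the root
    closest to zero is returned and the branch note records the other.
    Raises when |mu| exceeds the attainable range on the bracket.
    """
    ka = _kappa_a(colloid, buffer)
    if mu == 0.0:
        return ZetaResult(zeta=0.0, sigma_ek=0.0, kappa_a=ka)

    def f(z_mV: float) -> float:
        return mobility_from_zeta(z_mV, colloid, buffer, drag) - mu

    sign = 1.0 if mu > 0 else -1.0
    grid = sign * np.linspace(0.0, bracket_mV, 801)
    vals = np.array([f(z) for z in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            lo, hi = sorted((grid[i], grid[i + 1]))
            roots.append(float(brentq(f, lo, hi, xtol=tol)))
    if not roots:
        attainable = sign * float(np.max(sign * (vals + mu)))
        raise ValueError(
            f"mobility {mu:g} (1e-8 m2/Vs) is outside the attainable range of "
            f"the approximation on |zeta| <= {bracket_mV} mV "
            f"(extreme ~ {attainable:g}); the film may be outside its validity"
        )
    roots.sort(key=abs)
    zeta = roots[0]
    note = ""
    if len(roots) > 1:
        note = (
            f"second root at {roots[1]:.1f} mV inside the bracket "
            "(mobility non-monotonic in zeta); smallest |zeta| returned"
        )
    sigma = sigma_ek_from_zeta(zeta, colloid, buffer)
    return ZetaResult(zeta=zeta, sigma_ek=sigma, kappa_a=ka, branch_note=note)


def sigma_ek_from_zeta(
    zeta: float, colloid: ColloidSpec, buffer: BufferSolution
) -> float:
    """Electrokinetic charge density [e/nm2] from zeta [mV] (z = 1)."""
    ka = _kappa_a(colloid, buffer)
    med = buffer.medium
    kappa = ka / (colloid.radius * NM)  # 1/m
    kT = K_B * med.temperature
    y = E_CHARGE * zeta * MV / kT
    if y == 0.0:
        return 0.0
    half = math.sinh(y / 2.0)
    quarter_cosh = math.cosh(y / 4.0)
    bracket = (
        1.0
        + (1.0 / ka) * 2.0 / quarter_cosh**2
        + (1.0 / ka**2) * 8.0 * math.log(quarter_cosh) / half**2
    )
    sigma_si = (
        2.0 * EPS0 * med.relative_permittivity * kappa * kT / E_CHARGE
    ) * half * math.sqrt(bracket)
    return C_per_m2_to_e_per_nm2(sigma_si)


def zeta_from_sigma(
    sigma: float,
    colloid: ColloidSpec,
    buffer: BufferSolution,
    tol: float = 1e-3,
) -> float:
    """Numeric inverse of the charge–potential relation, zeta in mV.

    sigma_ek(zeta) is strictly increasing and unbounded, so the root is
    unique; the bracket is grown geometrically until it straddles it.
    """
    if not math.isfinite(sigma):
        raise ValueError("sigma must be finite")
    if sigma == 0.0:
        return 0.0

    def f(z_mV: float) -> float:
        return sigma_ek_from_zeta(z_mV, colloid, buffer) - sigma

    hi = 25.0 * (1.0 if sigma > 0 else -1.0)
    while f(hi) * (1.0 if sigma > 0 else -1.0) < 0:
        hi *= 2.0
        if abs(hi) > 1e5:  # pragma: no cover - physically unreachable
            raise RuntimeError("failed to bracket zeta")
    lo, hi = sorted((0.0, hi))
    return float(brentq(f, lo, hi, xtol=tol))


def complex_pI(curve: MobilityCurve) -> float:
    """Isoelectric point of a complex from its mobility-vs-pH curve.

    Linear interpolation between the unique pair of points bracketing
    the sign change; errors out if the curve never crosses zero or
    crosses more than once.
    """
    ph = curve.pH
    mu = curve.mobility
    crossings: list[float] = []
    for i in range(len(ph) - 1):
        a, b = mu[i], mu[i + 1]
        if a == 0.0:
            crossings.append(float(ph[i]))
        elif a * b < 0:
            crossings.append(float(ph[i] - a * (ph[i + 1] - ph[i]) / (b - a)))
    if mu[-1] == 0.0:
        crossings.append(float(ph[-1]))
    if not crossings:
        raise ValueError("mobility curve does not change sign; no pI in range")
    if len(crossings) > 1:
        raise ValueError(
            f"mobility curve changes sign more than once (at pH {crossings}); "
            "cannot assign a unique pI"
        )
    return crossings[0]
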