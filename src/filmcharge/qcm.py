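"""QCM-D trace reduction: Sauerbrey film mass, rigidity diagnostics, packing.

A quartz-crystal microbalance with dissipation monitoring reports, per odd
overtone n, the resonance-frequency shift Delta f_n and the dissipation
shift Delta D_n of a coated crystal.  For a rigid, thin film the Sauerbrey
relation

    m_f = -C * Delta f_n / n

maps the normalized frequency shift to the film's wet areal mass, with C
the mass-sensitivity constant of the crystal (about 18 ng cm^-2 Hz^-1 for
a 5 MHz AT-cut quartz).  The reduction here takes a trace to steady-state
per-overtone values, quantifies overtone dispersion (a viscoelasticity
diagnostic: a rigid film shows none), applies Sauerbrey with a caution
flag rather than a hard block when the film looks soft, and converts the
areal mass into an area per adsorbed protein for packing comparison with
the protein's own cross-section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import N_A
from .geometry import GyrationSummary

__all__ = [
    "QcmTrace",
    "FilmEstimate",
    "IsothermPoint",
    "PackingReport",
    "steady_state",
    "overtone_dispersion",
    "sauerbrey_mass",
    "sauerbrey_constant",
    "area_per_protein",
    "packing_comparison",
    "reduce_trace",
]

#: Default mass-sensitivity constant [ng cm^-2 Hz^-1] of a 5 MHz crystal.
DEFAULT_MASS_CONSTANT = 18.0
#: Rigidity thresholds: relative overtone dispersion and max |Delta D|.
RIGID_DISPERSION_MAX = 0.05
RIGID_DISSIPATION_MAX = 2e-6


@dataclass(frozen=True)
class QcmTrace:
    """Per-overtone Delta f_n(t) [Hz] and Delta D_n(t) series.

    ``delta_f`` and ``delta_D`` map odd overtone numbers to series of the
    same length as ``time`` [s].  ``events`` are labelled time marks
    (injection, rinse, concentration steps).  ``metadata`` may carry
    generator ground truth.
    """

    time: np.ndarray
    delta_f: Mapping[int, np.ndarray]
    delta_D: Mapping[int, np.ndarray]
    events: tuple[tuple[float, str], ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.size == 0:
            raise ValueError("empty trace")
        object.__setattr__(self, "time", t)
        overtones = sorted(self.delta_f)
        if not overtones:
            raise ValueError("trace has no overtones")
        if len(set(overtones)) != len(overtones) or any(n % 2 == 0 for n in overtones):
            raise ValueError("overtones must be distinct odd integers")
        for n in overtones:
            f = np.asarray(self.delta_f[n], dtype=float)
            d = np.asarray(self.delta_D[n], dtype=float)
            if f.shape != t.shape or d.shape != t.shape:
                raise ValueError(f"overtone {n}: series length mismatch with time")
        object.__setattr__(self, "delta_f", {n: np.asarray(self.delta_f[n], float) for n in overtones})
        object.__setattr__(self, "delta_D", {n: np.asarray(self.delta_D[n], float) for n in overtones})
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def overtones(self) -> tuple[int, ...]:
        return tuple(sorted(self.delta_f))


@dataclass(frozen=True)
class FilmEstimate:
    """Sauerbrey reduction of one trace segment."""

    areal_mass: float  # mg/m2
    dispersion_metric: float
    rigid: bool
    mass_constant: float  # ng cm^-2 Hz^-1
    delta_f_over_n: dict[int, float] = field(default_factory=dict)
    delta_D: dict[int, float] = field(default_factory=dict)
    stationary: bool = True
    caution: str = ""


@dataclass(frozen=True)
class IsothermPoint:
    """One stabilized point of an adsorption isotherm."""

    concentration: float  # mg/mL
    areal_mass: float  # mg/m2
    post_rinse: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class PackingReport:
    """Cross-section vs area-per-protein comparison for one film."""

    cross_section: float  # nm2
    area_per_protein: float  # nm2
    ratio: float
    verdict: str
    orientation: str


def steady_state(
    trace: QcmTrace,
    window: float | None = None,
    slope_threshold: float = 0.01,
) -> tuple[dict[int, float], dict[int, float], bool]:
    """Steady-state (Delta f_n / n, Delta D_n) per overtone.

    Averages each series over the final ``window`` seconds (default: the
    last 10% of the trace).  A windowed linear drift larger than
    ``slope_threshold`` times the signal magnitude flags the segment as
    non-stationary.  Returns (f_over_n, delta_D, stationary).
    """
    t = trace.time
    span = t[-1] - t[0]
    if window is None:
        window = 0.1 * span if span > 0 else 0.0
    if span > 0 and window >= span:
        raise ValueError("window must be shorter than the trace")
    mask = t >= t[-1] - window
    if not mask.any():
        mask = np.zeros_like(t, dtype=bool)
        mask[-1] = True
    f_over_n: dict[int, float] = {}
    d_mean: dict[int, float] = {}
    stationary = True
    for n in trace.overtones:
        seg = trace.delta_f[n][mask] / n
        f_over_n[n] = float(seg.mean())
        d_mean[n] = float(trace.delta_D[n][mask].mean())
        if seg.size >= 3:
            slope = np.polyfit(t[mask], seg, 1)[0]
            drift = abs(slope) * window
            if drift > slope_threshold * max(abs(f_over_n[n]), 1e-12):
                stationary = False
    return f_over_n, d_mean, stationary


def overtone_dispersion(values: Mapping[int, float] | Sequence[float]) -> float:
    """(max - min) / |mean| of Delta f_n / n across overtones."""
    vals = np.asarray(
        [values[k] for k in sorted(values)] if isinstance(values, Mapping) else list(values),
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("need at least two overtones for a dispersion metric")
    mean = vals.mean()
    if mean == 0.0:
        raise ValueError("mean of Delta f_n/n is zero; dispersion undefined")
    return float((vals.max() - vals.min()) / abs(mean))


def sauerbrey_mass(delta_f_over_n: float, C: float = DEFAULT_MASS_CONSTANT) -> float:
    """Areal film mass m_f = -C * (Delta f_n / n), returned in mg/m2.

    ``C`` is in ng cm^-2 Hz^-1 (1 ng/cm2 = 0.01 mg/m2).  Linear and odd
    in the frequency shift; adsorption (negative shift) gives a positive
    mass.
    """
    return -C * delta_f_over_n * 0.01


def sauerbrey_constant(
    fundamental_frequency: float = 5e6,
    quartz_density: float = 2648.0,
    quartz_shear_modulus: float = 2.947e10,
) -> float:
    """Mass-sensitivity constant C = sqrt(rho_q mu_q) / (2 f0^2), in
    ng cm^-2 Hz^-1.

    Defaults are AT-cut quartz at 5 MHz, giving ~17.7 (commonly quoted
    as 18).
    """
    if fundamental_frequency <= 0 or quartz_density <= 0 or quartz_shear_modulus <= 0:
        raise ValueError("crystal properties must be positive")
    c_si = math.sqrt(quartz_density * quartz_shear_modulus) / (
        2.0 * fundamental_frequency**2
    )  # kg m^-2 Hz^-1
    return c_si * 1e8  # -> ng cm^-2 Hz^-1


def area_per_protein(mf: float, Mw: float) -> float:
    """Area per adsorbed protein a_p = Mw / (NA * m_f), in nm2.

    ``Mw`` in kDa (kg/mol), ``mf`` in mg/m2.  At full monolayer coverage
    this is the footprint one molecule occupies.
    """
    if mf <= 0:
        raise ValueError("areal mass must be > 0")
    # Mw [kg/mol] / NA -> kg per molecule; mf in kg/m2 = 1e-6 * mg/m2.
    area_m2 = (Mw / N_A) / (mf * 1e-6)
    return area_m2 / 1e-18  # -> nm2


def packing_comparison(
    summary: GyrationSummary,
    ap: float,
    orientation: str = "flat",
    compact_band: tuple[float, float] = (0.8, 1.2),
) -> PackingReport:
    """Compare a protein's cross-section with its measured footprint.

    ``flat`` (or spherical) orientation uses a_c = pi Rg^2; ``upright``
    uses pi (R2^2 + R3^2), the two smallest gyration components.  The
    film is called compact when a_c / a_p falls inside ``compact_band``,
    sparse when the footprint is larger, crowded when smaller.
    """
    if orientation == "flat":
        ac = math.pi * summary.Rg**2
    elif orientation == "upright":
        ac = math.pi * (summary.components[1] + summary.components[2])
    else:
        raise ValueError("orientation must be 'flat' or 'upright'")
    ratio = ac / ap
    lo, hi = compact_band
    if lo <= ratio <= hi:
        verdict = "compact"
    elif ratio < lo:
        verdict = "sparse"
    else:
        verdict = "crowded"
    return PackingReport(
        cross_section=ac,
        area_per_protein=ap,
        ratio=ratio,
        verdict=verdict,
        orientation=orientation,
    )


def reduce_trace(
    trace: QcmTrace,
    C: float = DEFAULT_MASS_CONSTANT,
    window: float | None = None,
) -> FilmEstimate:
    """Full reduction: steady state -> dispersion -> rigidity -> Sauerbrey.

    The Sauerbrey mass uses the overtone-average Delta f_n / n.  A film
    failing the rigidity criteria is still reduced but carries a caution
    note, since for a viscoelastic film the Sauerbrey mass is only an
    estimate.
    """
    f_over_n, d_mean, stationary = steady_state(trace, window=window)
    vals = list(f_over_n.values())
    disp = overtone_dispersion(f_over_n) if len(vals) >= 2 else 0.0
    rigid = disp < RIGID_DISPERSION_MAX and max(
        abs(v) for v in d_mean.values()
    ) < RIGID_DISSIPATION_MAX
    mf = sauerbrey_mass(float(np.mean(vals)), C)
    caution = ""
    if not rigid:
        caution = (
            "film fails rigidity criteria (overtone dispersion or dissipation "
            "too high); Sauerbrey mass is approximate"
        )
    return FilmEstimate(
        areal_mass=mf,
        dispersion_metric=disp,
        rigid=rigid,
        mass_constant=C,
        delta_f_over_n=f_over_n,
        delta_D=d_mean,
        stationary=stationary,
        caution=caution,
    )
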