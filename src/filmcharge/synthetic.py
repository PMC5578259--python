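"""Seeded synthetic inputs with known ground truth.

Every generator here produces one of the inputs the analysis consumes —
coordinate clouds standing in for protein conformations, QCM-D traces,
and electrophoretic-mobility curves — from an explicit model with its
parameters recorded as metadata, so round-trip tests can compare the
recovered quantities against the injected truth instead of re-deriving
them from noisy output.  All randomness flows from the ``seed``
argument; the same seed reproduces bit-identical output.

Noise is Gaussian and i.i.d. per sample.  The default mobility noise
scale (5% relative) matches the typical run-to-run spread of
electrophoretic-mobility measurements on latex suspensions.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .electrokinetics import (
    ColloidSpec,
    DEFAULT_DRAG,
    MobilityCurve,
    mobility_from_zeta,
    zeta_from_sigma,
)
from .condensation import complex_bare_charge, effective_charge
from .geometry import CoordinateSet
from .physchem import BufferSolution, default_buffer
from .qcm import DEFAULT_MASS_CONSTANT, QcmTrace
from .titration import ChargeCurve

__all__ = [
    "make_ellipsoid_cloud",
    "make_chain",
    "make_qcm_trace",
    "make_mobility_curve",
    "synthetic_sequence",
    "SYNTHETIC_COMPOSITIONS",
]


def make_ellipsoid_cloud(
    semi_axes: Sequence[float],
    n_atoms: int = 1000,
    seed: int = 0,
    label: str = "ellipsoid",
) -> CoordinateSet:
    """Uniform unit-mass point cloud inside an ellipsoid (semi-axes in nm).

    The gyration-tensor eigenvalues converge to (a^2/5, b^2/5, c^2/5);
    a sphere of radius R gives Rg^2 -> 3 R^2 / 5.
    """
    axes = np.asarray(semi_axes, dtype=float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise ValueError("need three positive semi-axes")
    if n_atoms < 10:
        raise ValueError("need at least 10 atoms")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_atoms, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = rng.random(n_atoms) ** (1.0 / 3.0)
    pts = v * r[:, None] * axes
    return CoordinateSet(positions=pts, label=label)


def make_chain(
    n_beads: int,
    bond_length: float = 0.38,
    stiffness: float = 0.0,
    seed: int = 0,
    label: str = "chain",
) -> CoordinateSet:
    """Freely-rotating bead chain (bond length in nm).

    ``stiffness`` is the cosine of the fixed bond angle: 0 reproduces
    ideal-chain statistics (ensemble mean Rg^2 ~ n b^2 / 6), 1 is the
    rigid rod limit (collinear beads, asphericity 1).
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    if not (0.0 <= stiffness <= 1.0):
        raise ValueError("stiffness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    pos[1] = pos[0] + bond_length * d
    cos_t = stiffness
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
    for i in range(2, n_beads):
        if stiffness >= 1.0:
            new_d = d
        else:
            # orthonormal frame around the previous bond direction
            ref = np.array([1.0, 0.0, 0.0])
            if abs(d[0]) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = np.cross(d, ref)
            u /= np.linalg.norm(u)
            w = np.cross(d, u)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            new_d = cos_t * d + sin_t * (math.cos(phi) * u + math.sin(phi) * w)
        pos[i] = pos[i - 1] + bond_length * new_d
        d = new_d
    return CoordinateSet(positions=pos, label=label)


def make_qcm_trace(
    mf_target: float,
    tau: float = 120.0,
    overtones: Sequence[int] = (3, 5, 7, 9, 11, 13),
    dispersion: float = 0.0,
    noise_Hz: float = 0.0,
    mode: str = "monolayer",
    C: float = DEFAULT_MASS_CONSTANT,
    duration: float | None = None,
    dt: float = 2.0,
    seed: int = 0,
) -> QcmTrace:
    """Synthetic adsorption trace approaching a target areal mass [mg/m2].

    The normalized shift follows an exponential approach,
    Delta f_n/n(t) = -(mf/0.01C)(1 - e^(-t/tau))(1 + delta_n) + noise,
    with ``delta_n`` a linear overtone spread sized so the steady-state
    dispersion metric equals ``dispersion``.  ``multilayer`` mode adds an
    early overshoot pulse, an order-of-magnitude larger dissipation, and
    a rinse event after which 20% of the mass is lost — emulating the
    build-up and partial wash-off of a soft multilayer film.  Ground
    truth (mf before/after rinse, dispersion, mode) goes to metadata.
    """
    if mf_target <= 0:
        raise ValueError("target areal mass must be > 0")
    if mode not in ("monolayer", "multilayer"):
        raise ValueError("mode must be 'monolayer' or 'multilayer'")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = 15.0 * tau
    t = np.arange(0.0, duration + dt / 2, dt)
    f_steady = -mf_target / (0.01 * C)  # Hz, per overtone (normalized)
    n_ot = len(overtones)
    spread = (
        np.linspace(-0.5, 0.5, n_ot) * dispersion if n_ot > 1 else np.zeros(1)
    )
    rise = 1.0 - np.exp(-t / tau)
    rinse_time = 0.7 * duration
    rinse_loss = 0.2 if mode == "multilayer" else 0.0
    events: list[tuple[float, str]] = [(0.0, "injection")]
    delta_f: dict[int, np.ndarray] = {}
    delta_D: dict[int, np.ndarray] = {}
    d_scale = 4e-6 if mode == "multilayer" else 0.2e-6
    for k, n in enumerate(overtones):
        series = f_steady * rise * (1.0 + spread[k])
        d_series = d_scale * rise.copy()
        if mode == "multilayer":
            # reorganization overshoot shortly after injection
            pulse = 0.25 * abs(f_steady) * (t / tau) * np.exp(1.0 - t / tau)
            series -= pulse
            d_series += 1e-6 * (t / tau) * np.exp(1.0 - t / tau)
            after = t >= rinse_time
            relax = 1.0 - np.exp(-(t[after] - rinse_time) / (0.3 * tau))
            post = f_steady * (1.0 - rinse_loss) * (1.0 + spread[k])
            series[after] += (-series[after] + post) * relax
            d_series[after] *= 1.0 - 0.3 * relax
        if noise_Hz > 0:
            series = series + rng.normal(0.0, noise_Hz, size=t.size)
            d_series = d_series + rng.normal(0.0, 0.02e-6, size=t.size)
        delta_f[n] = series * n
        delta_D[n] = d_series
    if mode == "multilayer":
        events.append((rinse_time, "rinse"))
    return QcmTrace(
        time=t,
        delta_f=delta_f,
        delta_D=delta_D,
        events=tuple(events),
        metadata={
            "mf_target": mf_target,
            "mf_post_rinse": mf_target * (1.0 - rinse_loss),
            "dispersion": dispersion,
            "noise_Hz": noise_Hz,
            "mode": mode,
            "mass_constant": C,
            "tau": tau,
            "seed": seed,
        },
    )


def make_mobility_curve(
    charge_curve: ChargeCurve,
    ap: float,
    colloid: ColloidSpec,
    buffers: Sequence[BufferSolution] | None = None,
    noise: float = 0.0,
    drag: tuple[float, float] = DEFAULT_DRAG,
    seed: int = 0,
) -> MobilityCurve:
    """Forward-model a mobility-vs-pH curve from a titration charge curve.

    Per pH: sigma_0 = Q(pH)/a_p -> condensation (Bocquet rule) ->
    zeta from the charge–potential relation -> Ohshima mobility, then
    multiplicative Gaussian noise of relative scale ``noise``.  Ground
    truth (pI, per-pH sigma_eff and zeta) is stored in metadata.
    """
    grid = charge_curve.pH_grid
    if buffers is None:
        buffers = [default_buffer(float(ph)) for ph in grid]
    if len(buffers) != len(grid):
        raise ValueError("need one buffer per pH grid point")
    rng = np.random.default_rng(seed)
    mu = np.empty(grid.size)
    sigma_eff = np.empty(grid.size)
    zeta = np.empty(grid.size)
    for i, ph in enumerate(grid):
        sigma0 = complex_bare_charge(float(charge_curve.net_charge[i]), ap)
        res = effective_charge(sigma0, colloid, buffers[i], theory="bocquet")
        sigma_eff[i] = res.sigma_eff
        zeta[i] = zeta_from_sigma(res.sigma_eff, colloid, buffers[i])
        mu[i] = mobility_from_zeta(zeta[i], colloid, buffers[i], drag)
    if noise > 0:
        mu = mu * (1.0 + rng.normal(0.0, noise, size=mu.size))
    return MobilityCurve(
        pH=grid,
        mobility=mu,
        buffers=tuple(buffers),
        metadata={
            "pI": charge_curve.pI,
            "sigma_eff": sigma_eff,
            "zeta_mV": zeta,
            "noise": noise,
            "ap": ap,
            "seed": seed,
        },
    )


#: Titratable-residue compositions of SYNTHETIC stand-in sequences for the
#: three milk/serum proteins studied with this pipeline.  Counts follow the
#: literature amino-acid compositions of bovin beta-casein,
#: beta-lactoglobulin and serum albumin; everything else is inert filler.
#: These are synthetic surrogates, not the real sequences.
SYNTHETIC_COMPOSITIONS: dict[str, dict[str, int]] = {
    "beta_casein_like": {"D": 4, "E": 19, "H": 5, "K": 11, "R": 4, "Y": 4, "C": 0, "length": 209},
    "beta_lactoglobulin_like": {"D": 11, "E": 16, "H": 2, "K": 15, "R": 3, "Y": 4, "C": 5, "length": 162},
    "bsa_like": {"D": 40, "E": 59, "H": 17, "K": 59, "R": 23, "Y": 20, "C": 35, "length": 583},
}


def synthetic_sequence(composition: str | dict[str, int], seed: int = 0) -> str:
    """Build a SYNTHETIC one-letter sequence with a given titratable-residue
    composition, padded to length with Gly/Ala and shuffled.

    Only the counts of ionizable residues matter for a titration model
    that ignores sequence context, so a composition-matched surrogate
    titrates identically to any real sequence with those counts.
    """
    comp = (
        dict(SYNTHETIC_COMPOSITIONS[composition])
        if isinstance(composition, str)
        else dict(composition)
    )
    length = comp.pop("length")
    letters: list[str] = []
    for aa, count in comp.items():
        letters.extend(aa * count)
    if len(letters) > length:
        raise ValueError("composition exceeds target length")
    filler = length - len(letters)
    letters.extend("G" * (filler // 2) + "A" * (filler - filler // 2))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(letters))
    return "".join(letters[i] for i in order)
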