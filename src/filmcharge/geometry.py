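"""Size and shape descriptors of protein coordinate sets.

This module computes the structural observables used to characterize an
adsorbed protein film at desk scale: the mass-weighted radius of gyration
and its decomposition along the gyration-tensor principal axes, the
asphericity Delta and shape parameter S built from those eigenvalues,
least-squares (Kabsch) superposition and RMSD, Shrake-Rupley
solvent-accessible surface area, and density profiles normal to an
adsorbing surface with a percentile film-thickness estimate.

Eigenvalue convention
---------------------
Delta and S are defined on the three eigenvalues (lambda_1 >= lambda_2 >=
lambda_3) of the mass-weighted *gyration tensor* — i.e. the squared
principal radii of gyration R_i^2 with Rg^2 = sum lambda_i — not on the
inertia tensor:

    Delta = (3/2) * sum_i (lambda_i - lambda_m)^2 / (sum_i lambda_i)^2
    S     = 27 * prod_i (lambda_i - lambda_m) / (sum_i lambda_i)^3

with lambda_m the eigenvalue mean.  Only this convention reproduces the
canonical limits (sphere: Delta = 0, S = 0; thin rod: Delta = 1, S = 2)
and the published values for globular proteins; descriptions phrased in
terms of "principal moments of inertia" coincide with it only up to this
normalization choice, which is why it is spelled out here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "CoordinateSet",
    "GyrationSummary",
    "AlignmentResult",
    "DensityProfile",
    "gyration_analysis",
    "shape_descriptors",
    "kabsch_align",
    "rmsd",
    "sasa",
    "density_profile",
    "film_thickness",
]


@dataclass(frozen=True)
class CoordinateSet:
    """Atom positions (nm) with per-atom masses (amu) and optional radii (nm).

    ``backbone_flags`` marks backbone atoms for profile/RMSD selections.
    """

    positions: np.ndarray
    masses: np.ndarray | None = None
    radii: np.ndarray | None = None
    backbone_flags: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions must be an N x 3 array with N >= 1")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        n = pos.shape[0]
        masses = self.masses
        if masses is None:
            masses = np.ones(n)
        masses = np.asarray(masses, dtype=float)
        if masses.shape != (n,) or np.any(masses <= 0):
            raise ValueError("masses must be N positive values")
        object.__setattr__(self, "masses", masses)
        if self.radii is not None:
            radii = np.asarray(self.radii, dtype=float)
            if radii.shape != (n,) or np.any(radii < 0):
                raise ValueError("radii must be N non-negative values")
            object.__setattr__(self, "radii", radii)
        if self.backbone_flags is not None:
            flags = np.asarray(self.backbone_flags, dtype=bool)
            if flags.shape != (n,):
                raise ValueError("backbone_flags must be length N")
            object.__setattr__(self, "backbone_flags", flags)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (self.positions * m[:, None]).sum(axis=0) / m.sum()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoordinateSet":
        """Return a rigidly moved copy: x -> R x + t."""
        return CoordinateSet(
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
            masses=self.masses,
            radii=self.radii,
            backbone_flags=self.backbone_flags,
            label=self.label,
        )


@dataclass(frozen=True)
class GyrationSummary:
    """Gyration-tensor summary of one conformation.

    ``components`` are the squared principal radii (nm^2) in descending
    order; their sum equals Rg^2.  ``shape_defined`` is False for a
    degenerate (all-coincident) conformation, in which case asphericity
    and shape are None rather than NaN.
    """

    Rg: float
    components: tuple[float, float, float]
    asphericity: float | None
    shape: float | None
    principal_axes: np.ndarray
    center_of_mass: np.ndarray
    shape_defined: bool = True


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal rigid superposition of a mobile onto a reference set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class DensityProfile:
    """Normalized atom-probability histogram along one axis."""

    bin_edges: np.ndarray
    probability: np.ndarray
    axis: str = "z"

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        e = np.asarray(self.bin_edges, dtype=float)
        if p.size == 0 or e.size != p.size + 1:
            raise ValueError("need len(bin_edges) == len(probability) + 1 >= 2")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probability", p)
        object.__setattr__(self, "bin_edges", e)


def shape_descriptors(components: Sequence[float]) -> tuple[float, float]:
    """Asphericity Delta and shape parameter S from the three gyration
    eigenvalues (squared principal radii, nm^2, any order).

    Delta is 0 for a sphere and 1 for a thin rod; S is positive for
    prolate and negative for oblate conformations (range [-0.25, 2]).
    """
    lam = np.sort(np.asarray(components, dtype=float))[::-1]
    if lam.shape != (3,):
        raise ValueError("need exactly three eigenvalues")
    total = lam.sum()
    if total <= 0:
        raise ValueError("eigenvalues sum to zero; shape undefined")
    mean = total / 3.0
    dev = lam - mean
    delta = 1.5 * float(np.sum(dev**2)) / total**2
    s = 27.0 * float(np.prod(dev)) / total**3
    return delta, s


def gyration_tensor(coords: CoordinateSet) -> np.ndarray:
    """Mass-weighted gyration tensor (nm^2), symmetric 3x3."""
    m = coords.masses
    x = coords.positions - coords.center_of_mass
    return (x.T * m) @ x / m.sum()


def gyration_analysis(coords: CoordinateSet) -> GyrationSummary:
    """Radius of gyration, principal components, asphericity and shape.

    Eigenvalues are sorted descending; the principal-axes matrix has the
    eigenvectors as rows, each with its largest-magnitude component made
    positive, and is flipped to a proper rotation (det = +1).
    """
    if len(coords) < 2:
        raise ValueError("need at least 2 atoms for a defined shape")
    tensor = gyration_tensor(coords)
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    rg_sq = float(evals.sum())
    if rg_sq <= 0.0:
        return GyrationSummary(
            Rg=0.0,
            components=(0.0, 0.0, 0.0),
            asphericity=None,
            shape=None,
            principal_axes=np.eye(3),
            center_of_mass=coords.center_of_mass,
            shape_defined=False,
        )
    delta, s = shape_descriptors(evals)
    return GyrationSummary(
        Rg=math.sqrt(rg_sq),
        components=tuple(float(v) for v in evals),
        asphericity=delta,
        shape=s,
        principal_axes=axes,
        center_of_mass=coords.center_of_mass,
    )


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD sqrt(mean |a_i - b_i|^2) without alignment."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_align(mobile: CoordinateSet, reference: CoordinateSet) -> AlignmentResult:
    """Least-squares optimal rigid superposition (Kabsch) and its RMSD.

    Atoms correspond by index.  The returned transform maps mobile
    coordinates onto the reference frame: x -> R x + t.
    """
    if len(mobile) != len(reference):
        raise ValueError(
            f"atom count mismatch: {len(mobile)} vs {len(reference)}"
        )
    if len(mobile) < 3:
        raise ValueError("need at least 3 atoms to determine a rotation")
    x = mobile.positions
    y = reference.positions
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - yc, x - xc)
    R = rot.as_matrix()
    t = yc - R @ xc
    moved = x @ R.T + t
    return AlignmentResult(rotation=R, translation=t, rmsd=rmsd(moved, y))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    coords: CoordinateSet,
    probe_radius: float = 0.14,
    n_points: int = 960,
    per_atom: bool = False,
):
    """Shrake-Rupley solvent-accessible surface area in nm^2.

    Each atom is expanded by the probe radius and sampled with a fixed
    spherical quadrature; points buried inside any neighbour's expanded
    sphere are discarded.  Per-atom contributions sum to the total.
    """
    if coords.radii is None:
        raise ValueError("coordinate set has no atomic radii; SASA undefined")
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 32:
        raise ValueError("n_points < 32 gives a too-coarse quadrature")
    pos = coords.positions
    ext = coords.radii + probe_radius
    n = len(coords)
    unit = _sphere_points(n_points)
    d = cdist(pos, pos)
    areas = np.empty(n)
    for i in range(n):
        if ext[i] == 0.0:
            areas[i] = 0.0
            continue
        neighbours = np.nonzero((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        pts = pos[i] + ext[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= np.sum((pts - pos[j]) ** 2, axis=1) > ext[j] ** 2
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * accessible.mean()
    return areas if per_atom else float(areas.sum())


_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def density_profile(
    coords_list: Iterable[CoordinateSet],
    axis: str | int = "z",
    bin_width: float = 0.1,
    selection: str = "all",
    surface: float = 0.0,
) -> DensityProfile:
    """Probability distribution of atom distances from a surface plane.

    Distances are measured along ``axis`` from the plane at coordinate
    ``surface``; ``selection`` restricts to backbone atoms when flags
    are present.  The histogram is normalized to unit probability.
    """
    coords_list = list(coords_list)
    if not coords_list:
        raise ValueError("need at least one coordinate set")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if selection not in ("all", "backbone"):
        raise ValueError("selection must be 'all' or 'backbone'")
    ax = _AXES[axis]
    values = []
    for cs in coords_list:
        v = cs.positions[:, ax]
        if selection == "backbone":
            if cs.backbone_flags is None:
                raise ValueError("backbone selection requires backbone_flags")
            v = v[cs.backbone_flags]
        values.append(v - surface)
    vals = np.concatenate(values)
    if vals.size == 0:
        raise ValueError("selection matched no atoms")
    lo = math.floor(vals.min() / bin_width) * bin_width
    n_bins = max(1, int(math.ceil((vals.max() - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    prob = counts / counts.sum()
    return DensityProfile(bin_edges=edges, probability=prob, axis=str(axis))


def film_thickness(profile: DensityProfile, coverage_fraction: float = 0.90) -> float:
    """Film thickness as the width of the smallest interval [surface, t]
    containing ``coverage_fraction`` of the probability mass.

    Mass is accumulated bin by bin from the surface side with linear
    interpolation inside the bin where the target fraction is crossed.
    """
    if not (0.0 < coverage_fraction < 1.0):
        raise ValueError("coverage fraction must lie in (0, 1)")
    p = profile.probability
    edges = profile.bin_edges
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, coverage_fraction))
    if idx >= p.size:
        idx = p.size - 1
    prev = cum[idx - 1] if idx > 0 else 0.0
    frac_in_bin = (coverage_fraction - prev) / p[idx] if p[idx] > 0 else 1.0
    t = edges[idx] + frac_in_bin * (edges[idx + 1] - edges[idx])
    return float(t - edges[0])
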