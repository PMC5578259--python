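"""Gyration descriptors, Kabsch superposition, SASA, density profiles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filmcharge.geometry import (
    CoordinateSet,
    DensityProfile,
    density_profile,
    film_thickness,
    gyration_analysis,
    kabsch_align,
    sasa,
    shape_descriptors,
)
from filmcharge.synthetic import make_ellipsoid_cloud


def exact_cloud(components, masses=None):
    """Six unit-mass points whose gyration eigenvalues equal ``components``."""
    pts = []
    for i, lam in enumerate(components):
        v = np.zeros(3)
        v[i] = math.sqrt(3.0 * lam)
        pts.extend([v, -v])
    return CoordinateSet(positions=np.array(pts), masses=masses)


class TestShapeDescriptors:
    @pytest.mark.parametrize(
        "components, delta, s",
        [
            ((3.2, 3.0, 1.3), 0.058, -0.027),   # beta-casein-like
            ((6.4, 4.7, 3.9), 0.022, 0.0037),   # BSA-like
        ],
    )
    def test_globular_protein_components(self, components, delta, s):
        d, sp = shape_descriptors(components)
        assert d == pytest.approx(delta, rel=0.05)
        assert sp == pytest.approx(s, rel=0.15)

    def test_near_spherical_components_give_tiny_descriptors(self):
        # beta-lactoglobulin-like: one-decimal components are too coarse to
        # reproduce its published 8e-4 / -3e-5 exactly, but the descriptors
        # must come out of the same near-spherical order of magnitude
        d, s = shape_descriptors((1.6, 1.5, 1.4))
        assert 0 < d < 2e-3
        assert abs(s) < 1e-4

    def test_rod_limit(self):
        d, s = shape_descriptors((5.0, 0.0, 0.0))
        assert d == pytest.approx(1.0, rel=1e-12)
        assert s == pytest.approx(2.0, rel=1e-12)

    def test_sphere_limit(self):
        d, s = shape_descriptors((2.0, 2.0, 2.0))
        assert d == pytest.approx(0.0, abs=1e-15)
        assert s == pytest.approx(0.0, abs=1e-15)


class TestGyrationAnalysis:
    def test_components_reproduce_construction(self):
        g = gyration_analysis(exact_cloud((3.2, 3.0, 1.3)))
        assert np.allclose(g.components, (3.2, 3.0, 1.3), rtol=1e-12)
        assert g.Rg == pytest.approx(math.sqrt(7.5), rel=1e-12)

    def test_rg_decomposition_identity(self, rng):
        for _ in range(10):
            coords = CoordinateSet(
                positions=rng.normal(size=(30, 3)), masses=rng.uniform(1, 20, 30)
            )
            g = gyration_analysis(coords)
            assert sum(g.components) == pytest.approx(g.Rg**2, rel=1e-12)

    def test_descriptors_invariant_under_rigid_motion_and_mass_scale(self, rng):
        coords = CoordinateSet(
            positions=rng.normal(size=(40, 3)), masses=rng.uniform(1, 10, 40)
        )
        R = Rotation.random(random_state=7).as_matrix()
        moved = CoordinateSet(
            positions=coords.positions @ R.T + np.array([5.0, -2.0, 1.0]),
            masses=coords.masses * 3.7,
        )
        g0, g1 = gyration_analysis(coords), gyration_analysis(moved)
        assert g1.Rg == pytest.approx(g0.Rg, rel=1e-10)
        assert g1.asphericity == pytest.approx(g0.asphericity, rel=1e-9)
        assert g1.shape == pytest.approx(g0.shape, rel=1e-9)

    def test_uniform_ball_moments(self):
        cloud = make_ellipsoid_cloud((2.0, 2.0, 2.0), n_atoms=100_000, seed=42)
        g = gyration_analysis(cloud)
        assert g.Rg**2 == pytest.approx(3 * 2.0**2 / 5, rel=0.01)
        assert g.asphericity == pytest.approx(0.0, abs=0.01)

    def test_mass_weighting_matters(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        heavy_end = CoordinateSet(positions=pos, masses=np.array([10.0, 1.0, 1.0]))
        uniform = CoordinateSet(positions=pos)
        assert gyration_analysis(heavy_end).Rg < gyration_analysis(uniform).Rg

    def test_coincident_atoms_flag_undefined_shape(self):
        coords = CoordinateSet(positions=np.zeros((5, 3)))
        g = gyration_analysis(coords)
        assert g.Rg == 0.0
        assert not g.shape_defined
        assert g.asphericity is None and g.shape is None

    def test_principal_axes_are_proper_rotation(self, rng):
        g = gyration_analysis(
            CoordinateSet(positions=rng.normal(size=(25, 3)) * [3, 2, 1])
        )
        assert np.linalg.det(g.principal_axes) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.principal_axes @ g.principal_axes.T, np.eye(3), atol=1e-9)

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError):
            gyration_analysis(CoordinateSet(positions=np.zeros((1, 3))))


def _svd_kabsch_oracle(x, y):
    """Independent SVD superposition for cross-checking the alignment."""
    xc, yc = x - x.mean(0), y - y.mean(0)
    u, _, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    R = (u @ np.diag([1, 1, d]) @ vt).T
    aligned = xc @ R.T
    return float(np.sqrt(np.mean(np.sum((aligned - yc) ** 2, axis=1))))


class TestKabschAlign:
    def test_rigid_motion_recovered_exactly(self, rng):
        x = rng.normal(size=(20, 3))
        R = Rotation.random(random_state=5).as_matrix()
        moved = x @ R.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_align(CoordinateSet(moved), CoordinateSet(x))
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_atom_rmsd(self, rng):
        n = 16
        x = rng.normal(size=(n, 3)) * 5
        y = x.copy()
        d = 0.3
        # displace one atom of an otherwise identical pair; with many far
        # atoms the optimal transform stays ~identity and rmsd -> d/sqrt(N)
        y[0, 2] += d
        res = kabsch_align(CoordinateSet(y), CoordinateSet(x))
        assert res.rmsd == pytest.approx(d / math.sqrt(n), rel=0.05)

    def test_matches_independent_svd_oracle(self, rng):
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        res = kabsch_align(CoordinateSet(x), CoordinateSet(y))
        assert res.rmsd == pytest.approx(_svd_kabsch_oracle(x, y), abs=1e-6)

    def test_size_mismatch_and_underdetermined_errors(self):
        a = CoordinateSet(np.zeros((3, 3)) + np.eye(3))
        b = CoordinateSet(np.ones((4, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_align(a, b)
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_align(CoordinateSet(np.eye(2, 3)), CoordinateSet(np.eye(2, 3)))


def _two_sphere_accessible_area(r1, r2, d):
    """Analytic accessible area of two intersecting spheres."""
    if d >= r1 + r2:
        return 4 * math.pi * (r1**2 + r2**2)
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    return 4 * math.pi * r1**2 - 2 * math.pi * r1 * h1 + 4 * math.pi * r2**2 - 2 * math.pi * r2 * h2


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        coords = CoordinateSet(np.zeros((1, 3)), radii=np.array([0.15]))
        expected = 4 * math.pi * 0.29**2
        assert sasa(coords, probe_radius=0.14) == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_add(self):
        coords = CoordinateSet(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), radii=np.array([0.15, 0.18])
        )
        expected = 4 * math.pi * (0.29**2 + 0.32**2)
        assert sasa(coords, probe_radius=0.14) == pytest.approx(expected, rel=0.01)

    def test_overlapping_spheres_match_cap_geometry(self):
        r1, r2, probe, d = 0.17, 0.15, 0.14, 0.25
        coords = CoordinateSet(
            np.array([[0.0, 0, 0], [d, 0, 0]]), radii=np.array([r1, r2])
        )
        expected = _two_sphere_accessible_area(r1 + probe, r2 + probe, d)
        assert sasa(coords, probe_radius=probe) == pytest.approx(expected, rel=0.02)

    def test_per_atom_contributions_sum_to_total(self, rng):
        coords = CoordinateSet(
            rng.normal(size=(12, 3)) * 0.3, radii=np.full(12, 0.17)
        )
        per_atom = sasa(coords, per_atom=True)
        assert per_atom.sum() == pytest.approx(sasa(coords), rel=1e-12)

    def test_monotone_under_approach(self):
        def total(d):
            coords = CoordinateSet(
                np.array([[0.0, 0, 0], [d, 0, 0]]), radii=np.array([0.17, 0.17])
            )
            return sasa(coords, probe_radius=0.14)

        areas = [total(d) for d in (0.7, 0.5, 0.35, 0.2, 0.1)]
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_coarse_quadrature_rejected(self):
        coords = CoordinateSet(np.zeros((1, 3)), radii=np.array([0.15]))
        with pytest.raises(ValueError, match="quadrature"):
            sasa(coords, n_points=16)

    def test_missing_radii_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            sasa(CoordinateSet(np.zeros((1, 3))))


class TestDensityProfile:
    def test_single_point_occupies_one_bin(self):
        cs = CoordinateSet(np.array([[0.0, 0.0, 1.23]]))
        prof = density_profile([cs], bin_width=0.1)
        assert prof.probability.max() == pytest.approx(1.0)

    def test_uniform_slab_is_flat_and_spans_thickness(self, rng):
        z = rng.uniform(0.0, 3.0, size=20_000)
        cs = CoordinateSet(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        prof = density_profile([cs], bin_width=0.25)
        span = prof.bin_edges[-1] - prof.bin_edges[0]
        assert span == pytest.approx(3.0, abs=0.25)
        interior = prof.probability[1:-1]
        assert interior.std() / interior.mean() < 0.1

    def test_gaussian_cloud_recovers_sigma(self, rng):
        sigma = 0.8
        z = rng.normal(0.0, sigma, size=50_000)
        cs = CoordinateSet(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        prof = density_profile([cs], bin_width=0.05)
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        mean = np.sum(centers * prof.probability)
        est = math.sqrt(np.sum((centers - mean) ** 2 * prof.probability))
        assert est == pytest.approx(sigma, rel=0.03)

    def test_backbone_selection(self):
        cs = CoordinateSet(
            np.array([[0, 0, 0.0], [0, 0, 5.0]]),
            backbone_flags=np.array([True, False]),
        )
        prof = density_profile([cs], bin_width=0.5, selection="backbone")
        assert prof.bin_edges[-1] <= 0.5 + 1e-9

    def test_probabilities_normalized(self, rng):
        cs = CoordinateSet(rng.normal(size=(500, 3)))
        prof = density_profile([cs], bin_width=0.3)
        assert prof.probability.sum() == pytest.approx(1.0, abs=1e-9)


class TestFilmThickness:
    def test_uniform_slab_fraction(self):
        edges = np.linspace(0.0, 3.0, 31)
        prof = DensityProfile(edges, np.full(30, 1 / 30))
        assert film_thickness(prof, 0.90) == pytest.approx(2.7, abs=1e-9)

    def test_delta_profile_is_about_one_bin(self):
        prof = DensityProfile(np.array([0.0, 0.1]), np.array([1.0]))
        assert film_thickness(prof, 0.90) <= 0.1

    def test_two_layer_profile_exceeds_single_layer(self):
        edges = np.linspace(0.0, 6.0, 61)
        single = np.zeros(60)
        single[:30] = 1 / 30
        double = np.zeros(60)
        double[:30] = 0.5 / 30
        double[30:] = 0.5 / 30
        t1 = film_thickness(DensityProfile(edges, single), 0.9)
        t2 = film_thickness(DensityProfile(edges, double), 0.9)
        assert t2 > t1 + 2.0  # second layer adds its spacing

    def test_invalid_fraction_rejected(self):
        prof = DensityProfile(np.array([0.0, 0.1]), np.array([1.0]))
        with pytest.raises(ValueError):
            film_thickness(prof, 1.5)
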