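"""Schwarz enumeration, band table and fractional Legendre modes."""

import math

import numpy as np
import pytest
import sympy
from scipy import integrate

from surfnet.tiling import (FractionalMode, SchwarzTriple, SphericalPoint,
                            enumerate_schwarz_triples, fractional_harmonic,
                            fractional_legendre, hypergeometric_params,
                            mode_eigenvalue, mode_profile, norm_P,
                            norm_report, platonic_tiling_table,
                            spherical_triangle_area, tiling_solution)


class TestSchwarzEnumeration:
    def test_known_platonic_triples(self):
        triples = {(s.p, s.q, s.r) for s in enumerate_schwarz_triples(100)}
        non_dihedral = {t for t in triples if t[:2] != (2, 2)}
        assert non_dihedral == {(2, 3, 3), (2, 3, 4), (2, 3, 5)}
        assert (2, 3, 6) not in triples  # angle sum exactly pi: flat

    def test_dihedral_family_complete(self):
        triples = {(s.p, s.q, s.r) for s in enumerate_schwarz_triples(40)}
        for n in range(2, 41):
            assert (2, 2, n) in triples

    def test_invalid_triple_rejected(self):
        with pytest.raises(ValueError):
            SchwarzTriple(3, 3, 3)
        with pytest.raises(ValueError):
            SchwarzTriple(1, 2, 2)


class TestTriangleArea:
    def test_octant(self):
        assert spherical_triangle_area(np.pi / 2, np.pi / 2, np.pi / 2) == pytest.approx(np.pi / 2)

    @pytest.mark.parametrize("n", [1, 2, 5, 20])
    def test_wedge_half(self, n):
        # the (pi/2, pi/2, pi/(2n)) triangle has area pi/(2n)
        a = spherical_triangle_area(np.pi / 2, np.pi / 2, np.pi / (2 * n))
        assert a == pytest.approx(np.pi / (2 * n))

    def test_octants_tile_sphere(self):
        assert 8 * spherical_triangle_area(np.pi / 2, np.pi / 2, np.pi / 2) == pytest.approx(4 * np.pi)

    def test_flat_triangle_rejected(self):
        with pytest.raises(ValueError):
            spherical_triangle_area(np.pi / 3, np.pi / 3, np.pi / 3)

    @pytest.mark.parametrize("triple", [(2, 2, n) for n in range(2, 21)])
    def test_tile_count_times_area_covers_sphere(self, triple):
        p, q, r = triple
        area = spherical_triangle_area(np.pi / p, np.pi / q, np.pi / r)
        # a dihedral wedge is two such triangles; 2n wedges tile the sphere
        assert 4 * r * area == pytest.approx(4 * np.pi)


class TestHypergeometricParams:
    @pytest.mark.parametrize("pqr", [(2, 2, 4), (2, 3, 5), (2, 3, 3), (2, 2, 17)])
    def test_round_trip_to_angles(self, pqr):
        triple = SchwarzTriple(*pqr)
        a, b, c = hypergeometric_params(triple)
        angles = sorted([abs(1 - c), abs(c - a - b), abs(a - b)], reverse=True)
        want = sorted([1 / triple.p, 1 / triple.q, 1 / triple.r], reverse=True)
        assert angles == pytest.approx(want)

    def test_permutation_changes_assignment_not_multiset(self):
        a1 = hypergeometric_params(SchwarzTriple(2, 3, 4))
        # the branch maps p, q, r to fixed singular points; the angle
        # multiset is permutation invariant
        for params, pqr in [(a1, (2, 3, 4))]:
            a, b, c = params
            got = sorted([abs(1 - c), abs(c - a - b), abs(a - b)])
            assert got == pytest.approx(sorted(1 / x for x in pqr))

    def test_indices_non_integer_for_all_enumerated(self):
        for s in enumerate_schwarz_triples(12):
            a, b, c = hypergeometric_params(s)
            for val in (c, c - a - b, a - b):
                assert abs(val - round(val)) > 1e-9


class TestBandTable:
    def test_platonic_frequencies_and_amplitudes(self):
        rows = {r.name: r for r in platonic_tiling_table(1.0, 200.0, dihedral_n=20)}
        assert [rows[k].frequency for k in ("sphere", "tetrahedron", "cube",
                                            "octahedron", "dodecahedron",
                                            "icosahedron")] == [1, 4, 6, 8, 12, 20]
        assert [rows[k].amplitude for k in ("sphere", "tetrahedron", "cube",
                                            "octahedron", "dodecahedron",
                                            "icosahedron")] == [200, 50, 33, 25, 17, 10]
        assert rows["dihedral"].tile_count == 40
        assert rows["dihedral"].amplitude == 5
        assert rows["dihedral"].band == "gamma"

    def test_inverse_amplitude_frequency_law(self):
        rows = platonic_tiling_table(1.0, 200.0, dihedral_n=25)
        for r in rows:
            # frequency x amplitude == base product, within rounding
            assert abs(r.frequency * r.amplitude - 200.0) <= 0.5 * r.frequency

    def test_scales_propagate(self):
        rows = {r.name: r for r in platonic_tiling_table(2.0, 400.0, dihedral_n=None)}
        assert rows["cube"].frequency == 12
        assert rows["cube"].amplitude == 67  # round(400/6)


class TestModes:
    def test_eigenvalue_values(self):
        assert mode_eigenvalue(1) == pytest.approx(3.75)
        for n in range(1, 11):
            nu = 2 * n - 0.5
            assert mode_eigenvalue(n) == pytest.approx(nu * (nu + 1))
        with pytest.raises(ValueError):
            mode_eigenvalue(0)

    def test_mode_satisfies_legendre_equation(self):
        # symbolic-differentiation oracle: the closed-form profile solves
        # (1/sin)(sin y')' - mu^2 y / sin^2 + lam y = 0 with mu^2 = 1/4
        th = sympy.symbols("theta", positive=True)
        for n in (1, 2, 5, 10):
            y = sympy.sin(2 * n * th) / sympy.sqrt(sympy.sin(th))
            lam = mode_eigenvalue(n)
            resid = (sympy.diff(sympy.sin(th) * sympy.diff(y, th), th) / sympy.sin(th)
                     - y / (4 * sympy.sin(th) ** 2) + lam * y)
            f = sympy.lambdify(th, resid, "numpy")
            grid = np.linspace(0.2, np.pi - 0.2, 101)
            scale = np.max(np.abs(sympy.lambdify(th, lam * y, "numpy")(grid)))
            assert np.max(np.abs(f(grid))) / scale < 1e-8

    def test_rayleigh_quotient_matches_eigenvalue(self):
        theta = np.linspace(1e-4, np.pi - 1e-4, 200001)
        for n in (1, 2, 4):
            y = mode_profile(n, theta)
            dy = np.gradient(y, theta)
            num = integrate.simpson(dy**2 * np.sin(theta)
                                    + 0.25 * y**2 / np.sin(theta), x=theta)
            den = integrate.simpson(y**2 * np.sin(theta), x=theta)
            assert num / den == pytest.approx(mode_eigenvalue(n), rel=1e-4)

    def test_fractional_mode_container(self):
        m = FractionalMode(3)
        assert m.nu == 5.5 and m.mu == -0.5
        assert m.eigenvalue == pytest.approx(m.nu * (m.nu + 1))
        assert m.omega == pytest.approx(math.sqrt(35.75))


class TestFractionalLegendre:
    def hyp_series(self, nu, mu, x, terms=200):
        """Term-by-term Gauss series oracle."""
        z = (1.0 - x) / 2.0
        total, term = 0.0, 1.0
        for k in range(terms):
            total += term
            term *= (-nu + k) * (nu + 1 + k) / ((1 - mu + k) * (k + 1)) * z
        pref = ((1 + x) / (1 - x)) ** (mu / 2) / math.gamma(1 - mu)
        return pref * total

    def test_integer_case_reduces_to_legendre(self):
        x = np.linspace(-0.9, 0.9, 7)
        np.testing.assert_allclose(fractional_legendre(1.0, 0.0, x), x, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_half_order_closed_form_matches_series(self, n):
        nu = 2 * n - 0.5
        for x in (0.15, 0.4, 0.75, 0.9):
            got = fractional_legendre(nu, -0.5, x)
            want = self.hyp_series(nu, -0.5, x)
            assert got == pytest.approx(want, abs=1e-10)

    def test_reflection_structure_of_half_order_form(self):
        # P_nu^(1/2)(cos t) ~ cos((nu+1/2) t): reflection t -> pi - t maps
        # the oscillation onto cos((nu+1/2)pi - (nu+1/2)t) structure
        nu, t = 3.5, 0.7
        k = nu + 0.5
        lhs = fractional_legendre(nu, 0.5, math.cos(math.pi - t))
        pref = math.sqrt(2.0 / (math.pi * math.sin(t)))
        assert lhs == pytest.approx(pref * math.cos(k * (math.pi - t)), rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fractional_legendre(1.5, -0.5, 1.0)


class TestHarmonicAndTilingSolution:
    def test_modulus_independent_of_phi(self):
        vals = [abs(fractional_harmonic(2, SphericalPoint(1.1, phi)))
                for phi in (-2.0, 0.0, 1.0, 3.0)]
        assert np.ptp(vals) < 1e-14

    def test_equator_value(self):
        n = 1
        got = abs(fractional_harmonic(n, SphericalPoint(np.pi / 2, 0.3)))
        want = norm_P(n) ** -0.5 * (8 * np.pi) ** -0.5 * abs(np.cos(0.75 * np.pi))
        assert got == pytest.approx(want, rel=1e-12)

    def test_zeros_at_cosine_zeros(self):
        n = 2
        theta0 = (np.pi / 2) / (2 * n - 0.5)  # first zero of cos((2n-1/2) theta)
        assert abs(fractional_harmonic(n, SphericalPoint(theta0, 0.0))) < 1e-14

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            fractional_harmonic(1, SphericalPoint(0.0, 0.0))

    @pytest.mark.parametrize("n", range(1, 11))
    def test_boundary_vanishing_three_sides(self, n):
        lim = np.pi / (2 * n)
        phis = np.linspace(-lim, lim, 21)
        thetas = np.linspace(1e-3, np.pi / 2, 21)
        for phi in phis:
            assert abs(tiling_solution(n, np.pi / 2, phi)) < 1e-12
        for th in thetas:
            assert abs(tiling_solution(n, th, lim)) < 1e-12
            assert abs(tiling_solution(n, th, -lim)) < 1e-12

    def test_nodal_latitudes_count(self):
        # the colatitude factor cos((4n-1) theta') crosses zero 2n-1 times
        # strictly inside the tile
        for n in (1, 2, 3):
            th = np.linspace(1e-3, np.pi / 2 - 1e-3, 4001)
            vals = np.array([tiling_solution(n, t, 0.0) for t in th])
            crossings = np.sum(np.diff(np.sign(vals)) != 0)
            assert crossings == 2 * n - 1

    def test_single_sign_within_fundamental_subtile(self):
        # between the pole and the first nodal latitude the mode keeps
        # one sign throughout the tile interior
        for n in (1, 2, 4):
            first_zero = (np.pi / 2) / (4 * n - 1)
            th = np.linspace(1e-3, first_zero * 0.98, 25)
            ph = np.linspace(-np.pi / (2 * n) * 0.98, np.pi / (2 * n) * 0.98, 25)
            vals = np.array([[tiling_solution(n, t, p) for p in ph] for t in th])
            assert np.all(vals > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tiling_solution(1, 2.0, 0.0)
        with pytest.raises(ValueError):
            tiling_solution(2, 0.5, 1.0)


class TestNorm:
    def test_positive_for_small_modes(self):
        for n in range(1, 11):
            assert norm_P(n) > 0

    def test_quadrature_richardson_converges(self):
        for n in (1, 5, 10):
            coarse = norm_P(n, num_points=2001)
            fine = norm_P(n, num_points=4001)
            assert abs(fine - coarse) < 1e-8

    def test_normalized_harmonic_has_unit_norm(self):
        # integrate |Y|^2 over the sphere after normalization
        n = 2
        N = norm_P(n) ** -0.5
        theta = np.linspace(0.0, np.pi, 20001)
        integrand = (N**2 / (8 * np.pi)) * np.cos((2 * n - 0.5) * theta) ** 2
        total = 2 * np.pi * integrate.simpson(integrand, x=theta)
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_report_structure(self):
        rep = norm_report(3)
        assert rep["quadrature"] > 0 and rep["closed_form"] > 0
        assert rep["relative_discrepancy"] >= 0
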