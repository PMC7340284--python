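"""Fluid-side physics: kernel, equation of state, pair forces, density
evolution and trans-wall mass transfer."""

import numpy as np
import pytest
from scipy.integrate import quad

from cellsph import sph
from cellsph.interactions import build_neighbors


class TestKernel:
    def test_compact_support(self):
        h = 6.8e-6
        assert sph.kernel_value(2.5 * h, h) == 0.0
        assert sph.kernel_value(2.0 * h, h) == 0.0
        assert sph.kernel_value(0.5 * h, h) > 0.0

    def test_unit_integral_by_quadrature(self):
        # 3-D radial quadrature oracle: int W 4 pi r^2 dr = 1
        h = 1.7
        val, _ = quad(lambda r: sph.kernel_value(r, h) * 4 * np.pi * r**2,
                      0, 2 * h, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_printed_normalization_integrates_to_four_ninths(self):
        h = 1.0
        val, _ = quad(lambda r: sph.kernel_value(r, h, True) * 4 * np.pi * r**2,
                      0, 2 * h, limit=200)
        assert val == pytest.approx(4.0 / 9.0, abs=1e-6)

    def test_continuity_at_knots(self):
        h = 1.0
        eps = 1e-10
        assert sph.kernel_value(h - eps, h) == pytest.approx(
            sph.kernel_value(h + eps, h), rel=1e-6)
        assert sph.kernel_value(2 * h - eps, h) == pytest.approx(0.0, abs=1e-25)
        # C1 at both knots
        assert sph.kernel_derivative(h - eps, h) == pytest.approx(
            sph.kernel_derivative(h + eps, h), rel=1e-6)

    def test_gradient_zero_at_origin_and_antisymmetric(self):
        h = 2.0
        np.testing.assert_allclose(sph.kernel_gradient(np.zeros((1, 3)), h), 0.0)
        x = np.array([[0.3, -0.7, 1.1]])
        np.testing.assert_allclose(sph.kernel_gradient(x, h),
                                   -sph.kernel_gradient(-x, h))

    def test_gradient_matches_finite_difference(self, rng):
        h = 1.3
        x = rng.uniform(-1, 1, (50, 3))
        grad = sph.kernel_gradient(x, h)
        eps = 1e-7
        for d in range(3):
            dx = np.zeros(3)
            dx[d] = eps
            fd = (sph.kernel_value(np.linalg.norm(x + dx, axis=1), h)
                  - sph.kernel_value(np.linalg.norm(x - dx, axis=1), h)) / (2 * eps)
            np.testing.assert_allclose(grad[:, d], fd, rtol=1e-6, atol=1e-8)


class TestSmoothingLength:
    def test_identity_and_linear_scaling(self):
        assert sph.update_smoothing_length(1.0, 1.0, 6.8e-6) == 6.8e-6
        assert sph.update_smoothing_length(0.5, 1.0, 6.8e-6) == pytest.approx(3.4e-6)

    def test_monotone_in_diameter(self):
        hs = [sph.update_smoothing_length(d, 1.0, 1.0) for d in (0.5, 1.0, 2.0)]
        assert hs == sorted(hs)


class TestEquationOfState:
    def test_reference_density_returns_turgor(self):
        assert sph.eos_pressure(1000.0, 20e6, 1000.0, 200e3) == pytest.approx(200e3)

    def test_one_percent_compression(self):
        expect = 200e3 + 20e6 * (1.01**7 - 1)
        assert sph.eos_pressure(1010.0, 20e6, 1000.0, 200e3) == pytest.approx(expect)

    def test_strictly_increasing_in_density(self):
        rho = np.linspace(800, 1200, 50)
        p = sph.eos_pressure(rho, 20e6, 1000.0, 200e3)
        assert np.all(np.diff(p) > 0)


def _pair_data(pos, h):
    pairs = build_neighbors(pos, None, 2 * h).pairs
    return (pairs,) + sph.pair_geometry(pos, pairs, h)


class TestPairForces:
    def test_isolated_particle_feels_nothing(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.ones(2)
        rho = np.ones(2) * 1000
        P = np.ones(2) * 1e5
        f = sph.pressure_forces(m, rho, P, pairs, rij, r, dw)
        np.testing.assert_allclose(f, 0.0)

    def test_positive_pressure_pair_repels(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.ones(2)
        f = sph.pressure_forces(m, np.full(2, 1000.0), np.full(2, 1e5),
                                pairs, rij, r, dw)
        assert f[0, 0] < 0 < f[1, 0]
        np.testing.assert_allclose(f[0], -f[1])

    def test_separating_pair_is_decelerated_by_viscosity(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        vel = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.ones(2)
        f = sph.viscous_forces(m, np.full(2, 1000.0), vel, 0.1,
                               pairs, rij, r, dw)
        # force opposes the separation velocity of each member
        assert f[0, 0] > 0 > f[1, 0]

    def test_rigid_translation_is_force_and_density_rate_free(self, rng):
        pos = rng.uniform(0, 3, (40, 3))
        vel = np.tile([[0.3, -0.2, 0.1]], (40, 1))
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.full(40, 2.0)
        rho = np.full(40, 1000.0)
        f = sph.viscous_forces(m, rho, vel, 0.1, pairs, rij, r, dw)
        np.testing.assert_allclose(f, 0.0, atol=1e-18)
        drho = sph.density_rate(m, vel, rho, pairs, rij, r, dw)
        np.testing.assert_allclose(drho, 0.0, atol=1e-12)

    def test_momentum_conservation_to_roundoff(self, rng):
        pos = rng.uniform(0, 4, (120, 3))
        vel = rng.normal(0, 1, (120, 3))
        h = 1.2
        pairs, rij, r, dw = _pair_data(pos, h)
        m = rng.uniform(0.5, 2.0, 120)
        rho = rng.uniform(900, 1100, 120)
        P = rng.uniform(-1e5, 5e5, 120)
        fp = sph.pressure_forces(m, rho, P, pairs, rij, r, dw)
        fv = sph.viscous_forces(m, rho, vel, 0.1, pairs, rij, r, dw)
        scale = np.abs(fp).sum() + np.abs(fv).sum()
        assert np.abs(fp.sum(axis=0)).max() < 1e-13 * scale
        assert np.abs(fv.sum(axis=0)).max() < 1e-13 * scale

    def test_symmetric_lattice_interior_point_feels_no_pressure_force(self):
        # uniform density & pressure on a cubic lattice: interior net force ~ 0
        ax = np.arange(-3, 4, dtype=float)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        centre = np.flatnonzero(np.all(pos == 0, axis=1))[0]
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        n = pos.shape[0]
        f = sph.pressure_forces(np.ones(n), np.full(n, 1000.0),
                                np.full(n, 2e5), pairs, rij, r, dw)
        assert np.linalg.norm(f[centre]) < 1e-12 * np.abs(f).max()


class TestDensity:
    def test_approaching_pair_has_positive_density_rate(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        vel = np.array([[1.0, 0, 0], [-1.0, 0, 0]])  # approaching
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.ones(2)
        drho = sph.density_rate(m, vel, np.full(2, 1000.0), pairs, rij, r, dw)
        assert np.all(drho > 0)

    def test_mass_loss_term_reduces_density_of_static_particles(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        vel = np.zeros((2, 3))
        h = 1.0
        pairs, rij, r, dw = _pair_data(pos, h)
        m = np.ones(2)
        rho = np.full(2, 1000.0)
        dm = np.full(2, -0.1)
        drho = sph.density_rate(m, vel, rho, pairs, rij, r, dw, dm_dt=dm)
        np.testing.assert_allclose(drho, rho / m * dm)

    def test_summation_density_of_uniform_lattice_matches_cell_mass(self):
        # relaxed uniform packing: sum_j m W(r_ij) ~ m / spacing^3 within 5%
        s = 1.0
        h = 0.8188 * s  # the benchmark kernel-support per spacing
        ax = np.arange(-4, 5, dtype=float) * s
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        centre = pos[np.all(pos == 0, axis=1)][0]
        r = np.linalg.norm(pos - centre, axis=1)
        m = 2.0
        rho_sum = (m * sph.kernel_value(r, h)).sum()
        assert rho_sum == pytest.approx(m / s**3, rel=0.05)


class TestMassTransfer:
    def test_fresh_equilibrium_has_zero_flux(self):
        rate = sph.mass_transfer_rate(np.array([200e3]), -200e3,
                                      4 * np.pi * (75e-6) ** 2, 2.5e-6,
                                      np.array([1000.0]), 3082)
        np.testing.assert_allclose(rate, 0.0)

    def test_overpressure_drives_water_out(self):
        rate = sph.mass_transfer_rate(np.array([210e3]), -200e3,
                                      4 * np.pi * (75e-6) ** 2, 2.5e-6,
                                      np.array([1000.0]), 3082)
        assert rate[0] < 0

    def test_magnitude_of_ten_kilopascal_imbalance(self):
        area = 4 * np.pi * (75e-6) ** 2
        rate = sph.mass_transfer_rate(np.array([10e3]), 0.0, area, 2.5e-6,
                                      np.array([1000.0]), 3082)
        expect = -area * 2.5e-6 * 1000.0 * 1e4 / 3082
        assert rate[0] == pytest.approx(expect)
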