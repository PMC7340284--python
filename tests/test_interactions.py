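"""Neighbour search, Lennard-Jones wall-fluid contact, plate contact."""

import numpy as np
import pytest

from cellsph import interactions as inter


class TestNeighborSearch:
    def test_far_pair_is_empty(self):
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        t = inter.build_neighbors(pos, None, 1.0)
        assert t.n_pairs == 0

    def test_matches_all_pairs_oracle_on_random_cloud(self, rng):
        pos = rng.uniform(0, 1, (200, 3))
        cutoff = 0.18
        table = inter.build_neighbors(pos, None, cutoff)
        got = {tuple(sorted(p)) for p in table.pairs}
        # O(n^2) oracle
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        expect = {(i, j) for i in range(200) for j in range(i + 1, 200)
                  if d[i, j] <= cutoff}
        assert got == expect

    def test_two_set_search_matches_oracle(self, rng):
        a = rng.uniform(0, 1, (80, 3))
        b = rng.uniform(0, 1, (60, 3))
        cutoff = 0.22
        table = inter.build_neighbors(a, b, cutoff)
        got = {tuple(p) for p in table.pairs}
        d = np.linalg.norm(a[:, None] - b[None, :], axis=-1)
        expect = {(i, j) for i in range(80) for j in range(60)
                  if d[i, j] <= cutoff}
        assert got == expect

    def test_point_exactly_at_cutoff_included(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        t = inter.build_neighbors(pos, None, 1.0)
        assert t.n_pairs == 1  # closed-ball convention

    def test_no_self_pairs(self, rng):
        pos = rng.uniform(0, 1, (50, 3))
        t = inter.build_neighbors(pos, None, 0.5)
        assert np.all(t.pairs[:, 0] != t.pairs[:, 1])


class TestLennardJones:
    R0 = 5e-6
    F0 = 1e-14

    def test_repulsion_vanishes_at_and_beyond_equilibrium_gap(self):
        assert inter.lj_repulsion_magnitude(self.R0, self.R0, self.F0) == 0.0
        assert inter.lj_repulsion_magnitude(1.4 * self.R0, self.R0, self.F0) == 0.0

    def test_repulsion_at_half_gap(self):
        mag = inter.lj_repulsion_magnitude(self.R0 / 2, self.R0, self.F0)
        expect = self.F0 * (2**8 - 2**4) / (self.R0 / 2) ** 2
        assert mag == pytest.approx(expect)
        assert mag == pytest.approx(240 * self.F0 / (self.R0 / 2) ** 2)

    def test_overlap_cap_bounds_the_force(self):
        capped = inter.lj_repulsion_magnitude(0.0, self.R0, self.F0)
        at_cap = inter.lj_repulsion_magnitude(0.1 * self.R0, self.R0, self.F0)
        assert capped == at_cap
        assert np.isfinite(capped)

    def test_attraction_band_and_cutoffs(self):
        assert inter.lj_attraction_magnitude(self.R0, self.R0, self.F0) == 0.0
        assert inter.lj_attraction_magnitude(2 * self.R0, self.R0, self.F0) == 0.0
        assert inter.lj_attraction_magnitude(2.01 * self.R0, self.R0, self.F0) == 0.0
        assert inter.lj_attraction_magnitude(1.3 * self.R0, self.R0, self.F0) > 0.0

    def test_combined_force_is_continuous_at_the_knots(self):
        eps = 1e-9 * self.R0

        def net(r):
            return (inter.lj_repulsion_magnitude(r, self.R0, self.F0)
                    - inter.lj_attraction_magnitude(r, self.R0, self.F0))

        floor = 1e-7 * abs(net(0.5 * self.R0))
        for knot in (0.1 * self.R0, self.R0, 1.5 * self.R0):
            lo, hi = net(knot - eps), net(knot + eps)
            local = max(abs(lo), abs(hi), floor)
            assert abs(hi - lo) < 1e-4 * local

    def test_pair_forces_equal_and_opposite(self, rng):
        fluid = rng.uniform(0, 20e-6, (30, 3))
        wallp = rng.uniform(0, 20e-6, (20, 3))
        table = inter.build_neighbors(fluid, wallp, 10e-6)
        ff, fw = inter.wall_fluid_forces(fluid, wallp, table, 5e-6,
                                         2e-14, 1e-14)
        total = ff.sum(axis=0) + fw.sum(axis=0)
        scale = np.abs(ff).sum() + np.abs(fw).sum() + 1e-30
        assert np.abs(total).max() < 1e-12 * scale

    def test_no_pairs_in_range_gives_zero(self):
        fluid = np.zeros((3, 3))
        wallp = np.full((2, 3), 100e-6)
        table = inter.build_neighbors(fluid, wallp, 12e-6)
        ff, fw = inter.wall_fluid_forces(fluid, wallp, table, 5e-6, 2e-14, 1e-14)
        np.testing.assert_allclose(ff, 0.0)
        np.testing.assert_allclose(fw, 0.0)

    def test_approaching_fluid_particle_is_repelled_before_crossing(self):
        """Two-body integration: a fluid particle flying at a wall particle
        decelerates and turns around without passing it."""
        from cellsph.engine import integrate_particles

        r0, f0r = 5e-6, 1e-13
        wall_x = np.zeros(3)

        def force(x):
            d = x - wall_x
            r = np.linalg.norm(d, axis=1)
            mag = inter.lj_repulsion_magnitude(r, r0, f0r)
            return (mag / r)[:, None] * d

        x0 = np.array([[0.0, 0.0, 4.9e-6]])
        v0 = np.array([[0.0, 0.0, -2.0]])
        m = np.array([5.7e-13])
        x = x0.copy()
        v = v0.copy()
        zmin = x0[0, 2]
        for _ in range(200):
            x, v = integrate_particles(x, v, m, force, 1e-9, 10)
            zmin = min(zmin, x[0, 2])
        assert zmin > 0.0          # never crossed the wall plane
        assert x[0, 2] > zmin      # and was turned around


class TestPlates:
    def _plates(self):
        return inter.PlateSet(z_bottom=-80e-6, z_top=80e-6, speed=2.0,
                              half_x=75e-6, half_y=75e-6, r_pw=10e-6, kpw=1e3)

    def test_particle_outside_contact_range_feels_nothing(self):
        f, top, bot = inter.plate_wall_forces(np.array([[0.0, 0, 0]]),
                                              self._plates())
        np.testing.assert_allclose(f, 0.0)
        assert top == bot == 0.0

    def test_half_range_overlap_magnitude_and_direction(self):
        pl = self._plates()
        pos = np.array([[0.0, 0.0, pl.z_top - pl.r_pw / 2]])
        f, top, bot = inter.plate_wall_forces(pos, pl)
        # pushed away from the top plate, i.e. downward
        assert f[0, 2] == pytest.approx(-pl.kpw * pl.r_pw / 2)
        assert top == pytest.approx(pl.kpw * pl.r_pw / 2)

    def test_bottom_plate_pushes_up(self):
        pl = self._plates()
        pos = np.array([[0.0, 0.0, pl.z_bottom + pl.r_pw / 4]])
        f, top, bot = inter.plate_wall_forces(pos, pl)
        assert f[0, 2] == pytest.approx(pl.kpw * 0.75 * pl.r_pw)
        assert bot == pytest.approx(pl.kpw * 0.75 * pl.r_pw)

    def test_laterally_outside_particles_are_ignored(self):
        pl = self._plates()
        pos = np.array([[200e-6, 0.0, pl.z_top - 1e-6]])
        f, top, bot = inter.plate_wall_forces(pos, pl)
        np.testing.assert_allclose(f, 0.0)

    def test_reaction_balances_wall_forces(self, rng):
        pl = self._plates()
        pos = rng.uniform(-90e-6, 90e-6, (300, 3))
        f, top, bot = inter.plate_wall_forces(pos, pl)
        assert f[:, 2].sum() == pytest.approx(bot - top, abs=1e-12)

    def test_plate_advance_kinematics(self):
        pl = self._plates()
        z0 = pl.z_top
        for _ in range(10):
            pl.advance(1e-9)
        assert pl.z_top == pytest.approx(z0 - 10 * 2.0 * 1e-9)


class TestCalibration:
    def test_measured_gap_is_mean_nearest_distance(self):
        fluid = np.array([[0.0, 0, 0], [10e-6, 0, 0]])
        wallp = np.array([[3e-6, 0, 0], [14e-6, 0, 0]])
        assert inter.measure_contact_gap(fluid, wallp) == pytest.approx(3.5e-6)

    def test_strength_transmits_benchmark_patch_load(self):
        a1, r1 = inter.calibrate_lj_strengths(10e-6, 8e-6)
        assert a1 == pytest.approx(inter.ATTRACTION_CAL * r1)
        # calibrated contact at 0.9 r0 transmits the benchmark patch load
        mag = inter.lj_repulsion_magnitude(0.9 * 8e-6, 8e-6, r1)
        assert mag == pytest.approx(200e3 * (10e-6) ** 2, rel=1e-6)
        # strengths are contact properties: spacing-dependent only
        a2, r2 = inter.calibrate_lj_strengths(20e-6, 8e-6)
        assert r2 == pytest.approx(4 * r1)
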