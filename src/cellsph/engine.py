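"""Time integration and the two-stage drying / compression experiment.

The simulation advances with a kick-drift-kick (leapfrog) scheme under a
time step bounded by both the acoustic CFL condition of the weakly
compressible fluid and the stiffest spring attached to a wall particle.
A run passes through three stages:

``settle``
    The freshly built cell (fluid at reference density, wall unstretched)
    inflates to its turgid equilibrium.  Water crosses the wall following
    the osmotic imbalance (Pi = -P_T), so the fresh state ends with the
    wall stretched to the Young-Laplace balance and the fluid at the
    benchmark turgor.  The fully turgid edge widths L0' and the reference
    fluid mass X0 are captured at the end of this stage.

``drying``
    A moisture controller removes fluid mass at the rate set by the
    drying drive pressure until X/X0 reaches the target, after which the
    trans-wall flux is closed (for the fresh cell, the osmotic servo keeps
    holding the turgid equilibrium).  The turgor baseline of the equation
    of state declines with moisture content (turgor loss), and the wall
    contraction force shrinks the wall towards its dryness-dependent
    width.

``compression``
    Two lateral-extent-limited plates are placed around the cell; the
    bottom one is static and the top one descends at the configured
    speed.  The wall permeability drops to its compression-stage value so
    the cell is effectively closed, and observables are recorded every
    output interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from cellsph import sph, wall as wallmod, interactions as inter
from cellsph.geometry import (
    FluidState,
    WallMesh,
    assign_masses,
    build_wall_mesh,
    enclosed_volume,
    fill_fluid,
    initial_fluid_mass_from_geometry,
)
from cellsph.params import ModelParams


class NumericalError(RuntimeError):
    """Non-finite state detected; message names the step index."""


class DryingError(RuntimeError):
    """Moisture target not reached within the drying step budget."""


class EjectionError(RuntimeError):
    """Cell centroid left the lateral extent of the plates."""


# ---------------------------------------------------------------------------
# time-step bounds


def cfl_timestep(p: ModelParams, h: float | None = None,
                 sound_speed: float | None = None,
                 courant: float = 0.25) -> float:
    """Acoustic CFL bound dt <= C h / c with C = 0.25 and the equation of
    state's sound speed c = sqrt(7 K / rho0)."""
    h = p.smoothing_length_effective() if h is None else h
    c = p.sound_speed if sound_speed is None else sound_speed
    return courant * h / c


def stable_timestep(p: ModelParams) -> float:
    """Overall step bound: the CFL limit, the stiff-spring limit of the
    wall (contraction, plate and constitutive springs acting on one wall
    particle with ~6 incident edges) and the explicit viscous limit."""
    h = p.smoothing_length_effective()
    dt_cfl = cfl_timestep(p, h)
    m_w = p.wall_mass_total / p.wall_count_actual()
    k_edge = 2.0 * p.wall_shear_modulus * p.wall_thickness  # ~ d/dl of Eq spring
    k_sum = p.contraction_coefficient + p.plate_stiffness + k_edge
    dt_spring = math.sqrt(m_w / (6.0 * k_sum))
    dt_visc = 0.125 * h**2 * p.reference_density / p.fluid_viscosity
    return min(dt_cfl, dt_spring, dt_visc)


# ---------------------------------------------------------------------------
# state


@dataclass
class SimState:
    """The single evolving object: fluid + wall + plates + staging data."""

    fluid: FluidState
    wall: WallMesh
    params: ModelParams
    plates: inter.PlateSet | None = None
    time: float = 0.0
    stage: str = "settle"
    step_index: int = 0
    mass_turgid: float | None = None     # X0 reference, captured post-settle
    contraction_on: bool = False
    drying_frozen: bool = False
    drive_effective: float | None = None  # sized at first removal step
    freeze_step: int | None = None        # step index at flux close
    contact_height: float | None = None  # plate separation at first contact
    r0_lj: float = 0.0
    f0a: float = 0.0
    f0r: float = 0.0
    r_pw: float = 0.0
    diameter_initial: float = 0.0
    area_wall: float = 0.0
    lj_cap_count: int = 0
    escape_count: int = 0
    degenerate_hinge_count: int = 0
    plate_force_top: float = 0.0
    plate_force_bottom: float = 0.0
    # force / rate caches for the leapfrog scheme
    acc_fluid: np.ndarray | None = None
    acc_wall: np.ndarray | None = None
    drho: np.ndarray | None = None
    dmdt: np.ndarray | None = None
    components: dict = field(default_factory=dict)
    # neighbour caches
    _ff_pairs: np.ndarray | None = None
    _wf_table: inter.NeighborTable | None = None
    _steps_since_rebuild: int = 10**9

    @property
    def x_over_x0(self) -> float:
        ref = self.mass_turgid if self.mass_turgid else self.fluid.total_mass()
        return self.fluid.total_mass() / ref

    def turgor_reference(self) -> float:
        """Turgor baseline of the equation of state: the benchmark turgor
        for the fresh cell, declining with normalised moisture content
        once the turgid reference is set (turgor loss on drying)."""
        p = self.params
        if self.mass_turgid is None:
            return p.turgor_initial
        x = min(self.x_over_x0, 1.0)
        return p.turgor_initial * x ** p.turgor_moisture_exponent

    def cell_diameter(self) -> tuple[float, float]:
        """(vertical extent, mean principal extent) of the wall mesh."""
        ext = self.wall.positions.max(axis=0) - self.wall.positions.min(axis=0)
        return float(ext[2]), float(ext.mean())

    def smoothing_diameter(self) -> float:
        """Diameter driving the variable smoothing length: the vertical
        extent before plate contact, the mean principal extent after."""
        vert, mean = self.cell_diameter()
        return mean if self.contact_height is not None else vert


def turgid_stretch(p: ModelParams) -> float:
    """Young-Laplace pre-stretch of the fresh wall: the root of

        (G t0 / 3)(lambda - lambda^-5) = P_T (lambda r0) / 2,

    i.e. edge tension balancing the turgor load at the inflated radius.
    When the wall is too compliant to balance the turgor (no root below
    1.3) the cell starts near its rest geometry (stretch 1.02) and the
    settle-stage time cap bounds the subsequent inflation drift.
    """
    from scipy.optimize import brentq

    k = p.wall_shear_modulus * p.wall_thickness / 3.0
    load = p.turgor_initial * p.cell_radius / 2.0

    def g(lam: float) -> float:
        return k * (lam - lam**-5) - load * lam

    if p.turgor_initial <= 0:
        return 1.0
    if g(1.3) <= 0:  # compliant wall: no balance below the cap
        return 1.02
    return float(brentq(g, 1.0 + 1e-12, 1.3, xtol=1e-12))


def init_state(p: ModelParams, seed: int | None = None) -> SimState:
    """Build the initial cell from the configuration: icosphere wall,
    jittered-lattice fluid at the reference density, and geometric
    calibration of the contact parameters.

    Wall and fluid are pre-inflated by the analytic turgid stretch so the
    settle stage starts near the Young-Laplace equilibrium instead of
    waiting for the (slow) osmotic inflation from the rest geometry; edge
    rest lengths keep the built (unstretched) values.
    """
    seed = p.rng_seed if seed is None else seed
    mesh = build_wall_mesh(p.cell_radius, p.mesh_subdivisions, p.wall_mass_total)
    spacing = p.fluid_spacing()
    pts = fill_fluid(p.cell_radius, spacing, seed)
    lam = turgid_stretch(p)
    mesh.positions *= lam
    pts = pts * lam
    spacing = spacing * lam
    n_f = pts.shape[0]
    total = (p.fluid_mass_total if p.fluid_mass_total is not None
             else initial_fluid_mass_from_geometry(p.cell_radius,
                                                   p.reference_density))
    total = total * lam**3  # water taken up while inflating to turgidity
    fluid = FluidState(
        positions=pts,
        velocities=np.zeros_like(pts),
        masses=assign_masses(total, n_f),
        densities=np.full(n_f, p.reference_density),
        pressures=np.full(n_f, p.turgor_initial),
        smoothing_length=p.smoothing_length_effective(),
    )
    state = SimState(fluid=fluid, wall=mesh, params=p)
    state.r0_lj = (p.contact_range_lj if p.contact_range_lj is not None
                   else inter.measure_contact_gap(pts, mesh.positions))
    if p.lj_strength_attraction is None or p.lj_strength_repulsion is None:
        f0a, f0r = inter.calibrate_lj_strengths(spacing, state.r0_lj)
        state.f0a = p.lj_strength_attraction or f0a
        state.f0r = p.lj_strength_repulsion or f0r
    else:
        state.f0a = p.lj_strength_attraction
        state.f0r = p.lj_strength_repulsion
    state.r_pw = (p.contact_range_plate if p.contact_range_plate is not None
                  else spacing)
    state.diameter_initial = state.cell_diameter()[0]
    state.area_wall = mesh.surface_area()
    compute_forces(state)
    return state


# ---------------------------------------------------------------------------
# force assembly

_REBUILD_EVERY = 10
_PAD = 1.2


def _recover_escaped(state: SimState) -> None:
    """Re-insert fluid particles that slipped through the wall.

    At coarse resolutions a particle can occasionally shoot through a
    triangle face during the settle transient; once outside it has no
    neighbours, its state freezes and it corrupts every mean observable
    and the osmotic controller.  Escapees (strictly beyond the furthest
    wall vertex) are placed back inside the fluid body along their radial
    direction with zero velocity and the interior mean density; the event
    is counted as a warning.
    """
    fl, wl = state.fluid, state.wall
    centroid = wl.positions.mean(axis=0)
    wall_r = np.linalg.norm(wl.positions - centroid, axis=1)
    fluid_d = fl.positions - centroid
    fluid_r = np.linalg.norm(fluid_d, axis=1)
    # far-field trigger only: a particle hovering just outside the hull
    # is still coupled through the contact forces and recovers by itself
    esc = fluid_r > wall_r.max() + 2.0 * state.r0_lj
    if not esc.any():
        return
    inside = fluid_r <= wall_r.max()
    # clamp radially back to the wall hull; the contact forces then pull
    # the particle gently back into the fluid body
    unit = fluid_d[esc] / fluid_r[esc][:, None]
    fl.positions[esc] = centroid + unit * wall_r.max()
    fl.velocities[esc] = 0.0
    fl.densities[esc] = (fl.densities[inside].mean() if inside.any()
                         else state.params.reference_density)
    state.escape_count += int(esc.sum())


def _refresh_neighbors(state: SimState) -> None:
    if state._steps_since_rebuild < _REBUILD_EVERY:
        state._steps_since_rebuild += 1
        return
    state._steps_since_rebuild = 0
    _recover_escaped(state)
    h = state.fluid.smoothing_length
    state._ff_pairs = inter.build_neighbors(
        state.fluid.positions, None, 2.0 * h * _PAD).pairs
    state._wf_table = inter.build_neighbors(
        state.fluid.positions, state.wall.positions, 2.0 * state.r0_lj * _PAD)
    # cadence-coupled cache refreshes (cheap relative to pair forces)
    state.area_wall = state.wall.surface_area()
    d = state.smoothing_diameter()
    state.fluid.smoothing_length = sph.update_smoothing_length(
        d, state.diameter_initial, state.params.smoothing_length_effective())


def _osmotic_exchange(state: SimState) -> np.ndarray:
    """Zero-net-mass osmotic equilibration between fluid parcels:

        dm_i/dt = -(A_C L_p rho_i / n_f) (P_i - mean P).

    This is the per-particle pressure relaxation the trans-wall flux law
    performs around its osmotic set point, restricted to its mean-free
    part so it redistributes water between parcels without changing the
    cell's moisture content.  It keeps the pressure field uniform while
    the drying controller sets the net flux separately.
    """
    p = state.params
    fl = state.fluid
    pbar = float(np.mean(fl.pressures))
    return sph.mass_transfer_rate(fl.pressures, -pbar, state.area_wall,
                                  p.lp_drying, fl.densities, fl.n)


def _mass_transfer(state: SimState) -> np.ndarray:
    """Moisture controller: per-particle trans-wall mass rate for the
    current stage (see the module docstring)."""
    p = state.params
    fl = state.fluid
    if state.stage == "settle":
        # osmotic servo at the fresh equilibrium (Pi = -P_T), with a
        # permeability boost so the turgid state is reached quickly: the
        # settle stage is initialisation, not part of the experiment
        return sph.mass_transfer_rate(fl.pressures, -p.turgor_initial,
                                      state.area_wall,
                                      p.lp_drying * p.settle_lp_boost,
                                      fl.densities, fl.n)
    if state.stage == "drying":
        if state.drying_frozen:
            return _hold_pressure_floor(state)
        x = state.x_over_x0
        if p.target_moisture < 0.999 and x > p.target_moisture * (1.0 + 2e-4):
            # constant-drive removal, Pi_ext = -P_i + drive.  The drive is
            # sized so the removal fits comfortably inside the drying
            # window at the actual turgid mass and wall area (the
            # configured value is its floor), and tapers near the target
            # so the final approach stays quasi-static.
            if state.drive_effective is None:
                window = p.n_steps_drying * p.dt
                need = (1.0 - p.target_moisture) * state.mass_turgid
                gain = state.area_wall * p.lp_drying * p.reference_density
                state.drive_effective = max(p.drying_drive,
                                            need / (0.50 * window * gain))
            width = max(0.05, 0.1 * (1.0 - p.target_moisture))
            drive = state.drive_effective * min(
                1.0, max(0.35, (x - p.target_moisture) / width))
            removal = sph.mass_transfer_rate(fl.pressures,
                                             -fl.pressures + drive,
                                             state.area_wall, p.lp_drying,
                                             fl.densities, fl.n)
            # cavitation guard: parcels whose suction exceeds half the
            # (tapered) drive draw water back in, bounding the tension
            # the removal transient can build without rate-limiting the
            # removal itself (the X/X0 feedback still terminates the
            # stage at the target)
            threshold = max(50e3, 0.5 * drive)
            deficit = np.minimum(fl.pressures + threshold, 0.0)
            guard = sph.mass_transfer_rate(deficit, 0.0, state.area_wall,
                                           p.lp_drying, fl.densities, fl.n)
            return removal + guard
        if p.target_moisture >= 0.999:
            # fresh cell: keep holding the turgid equilibrium with the
            # same boosted servo the settle stage uses; influx stops once
            # the moisture ratio would leave its 1% band
            rate = sph.mass_transfer_rate(fl.pressures, -p.turgor_initial,
                                          state.area_wall,
                                          p.lp_drying * p.settle_lp_boost,
                                          fl.densities, fl.n)
            if x > 1.008:
                rate = np.minimum(rate, 0.0)
            return rate
        state.drying_frozen = True
        state.freeze_step = state.step_index
        return _hold_pressure_floor(state)
    # compression: the net trans-wall permeability falls to its real value
    return sph.mass_transfer_rate(fl.pressures, -state.turgor_reference(),
                                  state.area_wall, p.lp_compression,
                                  fl.densities, fl.n)


_HOLD_RESIDUAL_TURGOR = 1e3  # Pa


_HOLD_SETTLE_DELAY = 2e-6  # s of post-freeze mechanical settling


def _hold_pressure_floor(state: SimState) -> np.ndarray:
    """Dried-state hold: influx-only osmotic flux toward a small residual
    turgor (1 kPa), starting after a short post-freeze settling delay so
    the bounded influx budget lifts the static droplet instead of being
    absorbed by the decaying removal transient.

    The flux law is the trans-wall transfer with Pi set to minus the
    residual turgor, restricted to influx, so the dried steady state keeps
    a (slightly) positive pressure rather than drifting across zero with
    the last removal transient.  The mass this admits is bounded: influx
    stops if X/X0 exceeds the target by 0.5%, and restoring ~1 kPa costs a
    relative density change of ~1e-5, so the moisture ratio is untouched
    in practice.
    """
    p = state.params
    fl = state.fluid
    if state.freeze_step is not None and (
            (state.step_index - state.freeze_step) * p.dt < _HOLD_SETTLE_DELAY):
        return np.zeros(fl.n)
    if state.x_over_x0 > p.target_moisture * 1.008:
        return np.zeros(fl.n)
    deficit = np.minimum(fl.pressures, _HOLD_RESIDUAL_TURGOR)
    return sph.mass_transfer_rate(deficit, -_HOLD_RESIDUAL_TURGOR,
                                  state.area_wall, p.lp_drying,
                                  fl.densities, fl.n)


def compute_forces(state: SimState) -> None:
    """Assemble all force fields at the current configuration, refreshing
    pressures, the smoothing length, the mass-transfer rates and the
    density rate.  Individual components stay retrievable in
    ``state.components``."""
    p = state.params
    fl, wl = state.fluid, state.wall
    if not (np.isfinite(fl.positions).all() and np.isfinite(wl.positions).all()):
        raise NumericalError(f"non-finite positions at step {state.step_index}")
    _refresh_neighbors(state)

    dm_stage = _mass_transfer(state)
    if state.stage in ("drying", "compression"):
        dmdt = dm_stage + _osmotic_exchange(state)
    else:
        dmdt = dm_stage
    # Soft directional clamp bounding the per-particle mass spread to
    # [1/3, 3]x the mean water load (the boundary layer otherwise pumps
    # mass out of the interior without limit) ...
    mbar = fl.masses.mean()
    up = np.clip((3.0 * mbar - fl.masses) / (0.5 * mbar), 0.0, 1.0)
    dn = np.clip((fl.masses - mbar / 3.0) / (0.5 * mbar), 0.0, 1.0)
    dmdt = np.where(dmdt > 0, dmdt * up, dmdt * dn)
    # ... while the net trans-wall flux is re-pinned to the controller's
    # intent, so the mean-free exchange and the clamp cannot alter X/X0.
    dmdt += dm_stage.mean() - dmdt.mean()
    # hard rate bound: no parcel may change its mass by more than 2% per
    # step (a pathological pressure spike on a near-floor-mass parcel
    # otherwise overflows the density update through the rho dm/m term);
    # the bound is applied around a second mean re-pin because clipping
    # alone is asymmetric and would drift the net flux
    rate_cap = 0.02 * fl.masses / p.dt
    dmdt = np.clip(dmdt, -rate_cap, rate_cap)
    dmdt += dm_stage.mean() - dmdt.mean()
    dmdt = np.clip(dmdt, -rate_cap, rate_cap)
    fl.pressures = sph.eos_pressure(fl.densities, p.fluid_bulk_modulus,
                                    p.reference_density,
                                    state.turgor_reference())

    h = fl.smoothing_length
    pairs = state._ff_pairs
    rij, r, dw = sph.pair_geometry(fl.positions, pairs, h,
                                   p.kernel_printed_normalization)
    in_support = r <= 2.0 * h
    pairs, rij, r, dw = pairs[in_support], rij[in_support], r[in_support], dw[in_support]

    f_press = sph.pressure_forces(fl.masses, fl.densities, fl.pressures,
                                  pairs, rij, r, dw)
    f_visc = sph.viscous_forces(fl.masses, fl.densities, fl.velocities,
                                p.fluid_viscosity, pairs, rij, r, dw)
    drho = sph.density_rate(fl.masses, fl.velocities, fl.densities,
                            pairs, rij, r, dw, dm_dt=dmdt)
    cap = [0]
    # Wall-water adhesion fades with the hydration of the interface
    # (quadratic in relative water content, calibrated at the fresh
    # state); the load-bearing repulsion is moisture-independent.
    f0a = state.f0a
    if state.mass_turgid is not None:
        f0a *= min(state.x_over_x0, 1.0) ** 2
    f_lj_fluid, f_lj_wall = inter.wall_fluid_forces(
        fl.positions, wl.positions, state._wf_table, state.r0_lj,
        f0a, state.f0r, cap_counter=cap)
    state.lj_cap_count += cap[0]

    f_stiff = wallmod.stiff_forces(wl, p.wall_shear_modulus, p.wall_thickness)
    f_damp = wallmod.damping_forces(wl, p.wall_damping)
    degen = [0]
    f_bend = wallmod.bending_forces(wl, kb=p.bending_stiffness,
                                    strict=False, degenerate_counter=degen)
    state.degenerate_hinge_count += degen[0]
    if state.contraction_on:
        f_contr = wallmod.contraction_forces(
            wl, min(state.x_over_x0, 1.0), p.contraction_coefficient,
            p.contraction_a, p.contraction_b)
    else:
        f_contr = np.zeros_like(wl.positions)

    if state.plates is not None and state.plates.active:
        f_plate, top, bottom = inter.plate_wall_forces(wl.positions, state.plates)
        state.plate_force_top = top
        state.plate_force_bottom = bottom
        if top > 0.0 and state.contact_height is None:
            state.contact_height = state.plates.z_top - state.plates.z_bottom
    else:
        f_plate = np.zeros_like(wl.positions)
        state.plate_force_top = 0.0
        state.plate_force_bottom = 0.0

    total_fluid = f_press + f_visc + f_lj_fluid
    total_wall = f_stiff + f_damp + f_lj_wall + f_bend + f_contr + f_plate
    for name, arr in (("pressure", f_press), ("viscous", f_visc),
                      ("lj_fluid", f_lj_fluid), ("stiff", f_stiff),
                      ("damping", f_damp), ("lj_wall", f_lj_wall),
                      ("bending", f_bend), ("contraction", f_contr),
                      ("plate", f_plate)):
        state.components[name] = arr
    if not (np.isfinite(total_fluid).all() and np.isfinite(total_wall).all()):
        bad = [n for n, a in state.components.items()
               if not np.isfinite(a).all()]
        raise NumericalError(
            f"non-finite force component(s) {bad} at step {state.step_index}")

    state.acc_fluid = total_fluid / fl.masses[:, None]
    state.acc_wall = total_wall / wl.particle_mass
    state.drho = drho
    state.dmdt = dmdt


# ---------------------------------------------------------------------------
# integration

_MASS_FLOOR_FRACTION = 1e-4


def leapfrog_step(state: SimState, dt: float) -> SimState:
    """One kick-drift-kick update of the whole system.

    Velocities receive half-kicks around the position drift; densities and
    particle masses advance with their rates evaluated alongside the
    forces; pressures and the smoothing length are refreshed inside the
    force assembly.
    """
    fl, wl = state.fluid, state.wall
    if state.acc_fluid is None:  # e.g. freshly restored checkpoint
        compute_forces(state)
    fl.velocities += 0.5 * dt * state.acc_fluid
    wl.velocities += 0.5 * dt * state.acc_wall
    fl.positions += dt * fl.velocities
    wl.positions += dt * wl.velocities
    if state.plates is not None and state.plates.active:
        state.plates.advance(dt)

    floor = _MASS_FLOOR_FRACTION * fl.masses.mean()
    fl.masses = np.maximum(fl.masses + dt * state.dmdt, floor)
    fl.densities = np.maximum(fl.densities + dt * state.drho,
                              1e-3 * state.params.reference_density)

    compute_forces(state)
    fl.velocities += 0.5 * dt * state.acc_fluid
    wl.velocities += 0.5 * dt * state.acc_wall
    state.time += dt
    state.step_index += 1
    if state.step_index % 50 == 0:
        if not (np.isfinite(fl.positions).all() and np.isfinite(wl.positions).all()
                and np.isfinite(fl.densities).all()):
            raise NumericalError(f"non-finite state at step {state.step_index}")
    return state


def integrate_particles(x: np.ndarray, v: np.ndarray, m: np.ndarray,
                        force_fn: Callable[[np.ndarray], np.ndarray],
                        dt: float, n_steps: int):
    """The bare kick-drift-kick core on a plain particle set.

    This mirrors the ordering used by :func:`leapfrog_step` and exists so
    the integrator's conservation and reversibility can be checked against
    closed-form fixtures.
    """
    x = x.copy()
    v = v.copy()
    a = force_fn(x) / m[:, None]
    for _ in range(n_steps):
        v += 0.5 * dt * a
        x += dt * v
        a = force_fn(x) / m[:, None]
        v += 0.5 * dt * a
    return x, v


# ---------------------------------------------------------------------------
# stages


def run_settle(state: SimState, observer=None) -> SimState:
    """Integrate until the fresh cell is steady (bounded by the settle
    window), then capture the fully turgid reference: edge widths L0' and
    the reference fluid mass X0."""
    p = state.params
    dt = p.dt
    block = max(1, int(round(1e-6 / dt)))  # 1 us probing blocks
    n_min = int(round(p.settle_time / dt))
    n_max = max(n_min, int(round(p.settle_max_time / dt)))
    last_strain = _mean_strain(state.wall)
    last_mass = state.fluid.total_mass()
    steps = 0
    while steps < n_max:
        for _ in range(min(block, n_max - steps)):
            leapfrog_step(state, dt)
            if observer:
                observer(state)
        steps = state.step_index
        strain = _mean_strain(state.wall)
        mass = state.fluid.total_mass()
        p_ok = (p.turgor_initial <= 0
                or abs(float(np.mean(state.fluid.pressures)) - p.turgor_initial)
                < 0.02 * p.turgor_initial)
        steady = (abs(strain - last_strain) < 5e-4
                  and abs(mass - last_mass) / mass < 1e-3 and p_ok)
        last_strain, last_mass = strain, mass
        if steps >= n_min and steady:
            break
    # capture the fully turgid relaxed state
    state.wall.rest_width = state.wall.edge_lengths()
    state.mass_turgid = state.fluid.total_mass()
    state.contraction_on = True
    state.stage = "drying"
    return state


def run_drying(state: SimState, observer=None) -> SimState:
    """Drying stage: integrate the configured number of steps while the
    moisture controller takes X/X0 to the target and the cell re-settles.

    Raises :class:`DryingError` if the target is not reached within the
    step budget (reporting the closest X/X0 achieved).
    """
    p = state.params
    if state.stage == "settle":
        run_settle(state, observer)
    dt = p.dt
    for _ in range(p.n_steps_drying):
        leapfrog_step(state, dt)
        if observer:
            observer(state)
    x = state.x_over_x0
    if abs(x - p.target_moisture) > 0.01 * max(p.target_moisture, 1e-6):
        raise DryingError(
            f"moisture target {p.target_moisture} not reached within "
            f"{p.n_steps_drying} steps; closest X/X0 = {x:.4f}")
    return state


def place_plates(state: SimState) -> inter.PlateSet:
    """Plates around the current cell: the bottom plane just touching the
    lowest wall particle (zero initial force), the top plane above the cell
    by the configured gap (default 10% of the current cell height)."""
    p = state.params
    zmin = float(state.wall.positions[:, 2].min())
    zmax = float(state.wall.positions[:, 2].max())
    gap = (p.plate_gap_initial if p.plate_gap_initial is not None
           else 0.1 * (zmax - zmin))
    return inter.PlateSet(
        z_bottom=zmin - state.r_pw,
        z_top=zmax + gap,
        speed=p.plate_speed,
        half_x=p.plate_size[0] / 2.0,
        half_y=p.plate_size[1] / 2.0,
        r_pw=state.r_pw,
        kpw=p.plate_stiffness,
    )


def run_compression(state: SimState, observer=None) -> SimState:
    """Compression stage: the top plate descends at the configured speed
    for the configured number of steps while the cell is effectively
    closed (compression-stage permeability)."""
    p = state.params
    state.stage = "compression"
    state.plates = place_plates(state)
    state._steps_since_rebuild = 10**9  # force a neighbour refresh
    compute_forces(state)
    dt = p.dt
    check = max(1, p.output_every)
    for k in range(p.n_steps_compression):
        leapfrog_step(state, dt)
        if observer:
            observer(state)
        if k % check == 0:
            c = state.wall.positions.mean(axis=0)
            if abs(c[0]) > state.plates.half_x or abs(c[1]) > state.plates.half_y:
                raise EjectionError(
                    f"cell centroid left the plate extent at step {state.step_index}")
    return state


def _mean_strain(mesh: WallMesh) -> float:
    return float(np.mean(mesh.edge_lengths() / mesh.rest_length - 1.0))


@dataclass
class ExperimentResult:
    state: SimState
    records: "object"            # pandas DataFrame of TimeSeriesRecord rows
    summary: dict


def run_experiment(p: ModelParams, seed: int | None = None,
                   snapshot_dir=None) -> ExperimentResult:
    """Full experiment: settle -> drying -> compression, with observables
    recorded every ``output_every`` steps and optional snapshot output at
    stage boundaries.  Deterministic given the seed."""
    from cellsph import observables as obs
    from cellsph import io as cio

    state = init_state(p, seed)
    recorder = obs.Recorder(state, every=p.output_every)
    run_settle(state, recorder)
    if snapshot_dir is not None:
        cio.write_snapshot(state, snapshot_dir, tag="settled")
    run_drying(state, recorder)
    if snapshot_dir is not None:
        cio.write_snapshot(state, snapshot_dir, tag="dried")
    run_compression(state, recorder)
    if snapshot_dir is not None:
        cio.write_snapshot(state, snapshot_dir, tag="compressed")
    df = recorder.frame()
    summary = {
        "x_over_x0": state.x_over_x0,
        "final_mean_strain": _mean_strain(state.wall),
        "final_volume": enclosed_volume(state.wall.positions,
                                        state.wall.triangles),
        "lj_cap_count": state.lj_cap_count,
        "escape_count": state.escape_count,
        "degenerate_hinge_count": state.degenerate_hinge_count,
        "steps": state.step_index,
    }
    return ExperimentResult(state=state, records=df, summary=summary)
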