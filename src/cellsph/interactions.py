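"""Cross-domain couplings: neighbour search, Lennard-Jones wall-fluid
contact and the moving-plate contact force.

The LJ equilibrium gap r0 and the contact strengths are geometric
calibration quantities rather than measured material constants: by
default r0 is the mean wall-fluid nearest-neighbour distance measured at
initialisation, and the strengths are scaled so that a contact compressed
to 0.9 r0 transmits the turgor-pressure load carried by one fluid
particle's surface patch.  Both are overridable in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from cellsph._accel import row_norms, scatter_add_vec


@dataclass
class PlateSet:
    """Two horizontal compression plates; the bottom one is static, the top
    one moves downward at ``speed``."""

    z_bottom: float
    z_top: float
    speed: float               # m/s, downward
    half_x: float
    half_y: float
    r_pw: float                # contact range, m
    kpw: float                 # contact stiffness, N/m
    active: bool = True

    def advance(self, dt: float) -> None:
        self.z_top -= self.speed * dt
        if self.z_top <= self.z_bottom:
            raise RuntimeError("top plate reached the bottom plate")


@dataclass
class NeighborTable:
    """Pair lists for one cutoff; pairs are stored once with i < j (same-set
    search) or as (index_a, index_b) for two-set searches."""

    pairs: np.ndarray           # (n, 2) int
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def build_neighbors(positions_a: np.ndarray, positions_b: np.ndarray | None,
                    cutoff: float) -> NeighborTable:
    """All pairs with separation <= cutoff (closed ball), via k-d trees.

    With ``positions_b=None`` the search is within one set and each pair
    appears once with first index smaller.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree_a = cKDTree(positions_a)
    if positions_b is None:
        pairs = tree_a.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            pairs = np.empty((0, 2), dtype=np.int64)
        return NeighborTable(pairs=np.ascontiguousarray(pairs, dtype=np.int64),
                             cutoff=cutoff)
    tree_b = cKDTree(positions_b)
    coo = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    pairs = np.column_stack([coo.row, coo.col]).astype(np.int64)
    return NeighborTable(pairs=pairs, cutoff=cutoff)


def lj_repulsion_magnitude(r, r0: float, f0r: float, cap_at: float = 0.1,
                           force_ceiling: float | None = None):
    """Short-range contact repulsion

        f(r) = f0r [ (r0/r)^8 - (r0/r)^4 ] / r^2   for r <= r0, else 0,

    clamped below ``cap_at * r0`` so that pathological overlaps remain
    integrable with a fixed time step.  ``force_ceiling`` optionally
    bounds the magnitude outright; the engine passes ~80x the calibrated
    contact load there so a deep penetration is recoverable within a few
    steps instead of explosive.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    r = np.asarray(r, dtype=float)
    rc = np.maximum(r, cap_at * r0)
    q = r0 / rc
    mag = f0r * (q**8 - q**4) / rc**2
    if force_ceiling is not None:
        mag = np.minimum(mag, force_ceiling)
    return np.where(r <= r0, mag, 0.0)


_ATTRACTION_BAND = 0.5   # adhesion band width in units of r0
ATTRACTION_CAL = 8.0     # attraction:repulsion strength constant ratio


def lj_attraction_magnitude(r, r0: float, f0a: float):
    """Mirrored short-range contact adhesion, active on r0 < r < 1.5 r0:

        f(r) = f0a [ (r0/r)^4 - (r0/r)^8 ] (3 - 2 r/r0) / r^2,

    vanishing at r = r0 (continuity with the repulsive branch) and tapered
    to zero at the band edge, so the combined contact force is continuous
    on (0, inf) and zero at and beyond 2 r0.  The attractive law is a
    modelling choice isolated here (only its strength constant is a
    benchmark quantity); the short band anchors the wall to the adjacent
    fluid layer at contact but releases it when the drying cell shrinks
    away, instead of dragging the fluid along as a stuck shell.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    b = _ATTRACTION_BAND
    r = np.asarray(r, dtype=float)
    safe = np.where(r > 0, r, r0)
    q = r0 / safe
    taper = (1.0 + b - safe / r0) / b
    mag = f0a * (q**4 - q**8) * taper / safe**2
    return np.where((r > r0) & (r < (1.0 + b) * r0), mag, 0.0)


def measure_contact_gap(fluid_pos: np.ndarray, wall_pos: np.ndarray) -> float:
    """Mean wall-to-nearest-fluid distance at initialisation: the default
    LJ equilibrium gap r0."""
    d, _ = cKDTree(fluid_pos).query(wall_pos, k=1)
    return float(np.mean(d))


_CONTACT_PRESSURE_SCALE = 200e3  # Pa, the benchmark fresh-cell turgor


def calibrate_lj_strengths(fluid_spacing: float,
                           r0: float) -> tuple[float, float]:
    """Default LJ strength constants.

    Scaled so a contact compressed to 0.9 r0 carries the benchmark turgor
    load on one fluid particle's surface patch (200 kPa * spacing^2); the
    strengths are material contact properties and deliberately do not
    follow the configured turgor, so a turgor sweep varies only the
    turgor.  The attraction anchors the wall in the contact potential
    well on both sides; its strength constant is ATTRACTION_CAL times the
    repulsion's, set so the settled fresh wall sits at the Young-Laplace
    stretch (a physical consistency calibration of the short-band
    adhesion).
    """
    # bracket term of the repulsion at r = 0.9 r0 is ~0.99/r0^2 * ...
    q = 1.0 / 0.9
    bracket = (q**8 - q**4) / (0.9 * r0) ** 2
    f0r = _CONTACT_PRESSURE_SCALE * fluid_spacing**2 / bracket
    return ATTRACTION_CAL * f0r, f0r


def wall_fluid_forces(fluid_pos, wall_pos, table: NeighborTable, r0: float,
                      f0a: float, f0r: float,
                      cap_counter: list | None = None):
    """LJ contact forces between wall and fluid particle pairs.

    Returns ``(f_fluid, f_wall)``; the pair force acts along the pair unit
    vector, equal and opposite on the two members, so the coupling injects
    no net momentum.
    """
    f_fluid = np.zeros_like(fluid_pos)
    f_wall = np.zeros_like(wall_pos)
    if table.n_pairs == 0:
        return f_fluid, f_wall
    i, k = table.pairs[:, 0], table.pairs[:, 1]
    d = fluid_pos[i] - wall_pos[k]
    r = row_norms(d)
    live = r <= 2.0 * r0  # pair table may carry a rebuild-padding margin
    i, k, d, r = i[live], k[live], d[live], r[live]
    if cap_counter is not None:
        cap_counter[0] += int(np.sum(r < 0.1 * r0))
    rep = lj_repulsion_magnitude(r, r0, f0r,
                                 force_ceiling=100.0 * f0r / r0**2)
    att = lj_attraction_magnitude(r, r0, f0a)
    # repulsion pushes the pair apart, attraction pulls it together
    mag = rep - att
    safe = np.where(r > 0, r, 1.0)
    f = (mag / safe)[:, None] * d
    scatter_add_vec(f_fluid, i, f)
    scatter_add_vec(f_wall, k, -f)
    return f_fluid, f_wall


def plate_wall_forces(wall_pos: np.ndarray, plates: PlateSet):
    """Vertical plate contact F = -k_pw * dx_pw on wall particles inside a
    plate's lateral extent and within r_pw of its plane.

    Returns the per-particle force array and the reactions (top, bottom)
    accumulated on each plate; the reaction is the equal and opposite of
    the total force the plate exerts on the wall.
    """
    f = np.zeros_like(wall_pos)
    if not plates.active:
        return f, 0.0, 0.0
    lateral = (np.abs(wall_pos[:, 0]) <= plates.half_x) & (
        np.abs(wall_pos[:, 1]) <= plates.half_y)
    z = wall_pos[:, 2]

    # Top plate: particles below its plane within r_pw are pushed down.
    dist_top = plates.z_top - z
    top = lateral & (dist_top >= 0) & (dist_top < plates.r_pw)
    f_top = plates.kpw * (plates.r_pw - dist_top[top])
    f[top, 2] -= f_top
    # Bottom plate: particles above its plane within r_pw are pushed up.
    dist_bot = z - plates.z_bottom
    bot = lateral & (dist_bot >= 0) & (dist_bot < plates.r_pw)
    f_bot = plates.kpw * (plates.r_pw - dist_bot[bot])
    f[bot, 2] += f_bot
    return f, float(f_top.sum()), float(f_bot.sum())
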