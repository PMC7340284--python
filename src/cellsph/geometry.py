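"""Synthetic cell geometry: triangulated spherical wall and fluid packing.

The discretisation procedure behind the benchmark particle counts is not
documented, so the package generates its own: an icosphere (subdivided
icosahedron projected to the sphere) for the wall and a jittered cubic
lattice for the interior fluid.  Intensive observables are expected to be
robust to this choice; a resolution-convergence test enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class WallMesh:
    """Coarse-grained wall state: particle kinematics plus the fixed
    triangle topology, edge rest data and bending (hinge) adjacency.

    ``rest_width`` holds L0', the edge length at the fully turgid relaxed
    state that the moisture-driven contraction force shrinks towards; it is
    captured by the engine once the fresh cell has settled.
    """

    positions: np.ndarray          # (V, 3) m
    velocities: np.ndarray         # (V, 3) m/s
    particle_mass: float           # kg, equal per particle
    triangles: np.ndarray          # (F, 3) int, outward winding
    edges: np.ndarray              # (E, 2) int
    rest_length: np.ndarray        # (E,) m  -- l0
    rest_width: np.ndarray         # (E,) m  -- L0', captured post-settle
    hinge_faces_a: np.ndarray      # (E, 3) int: first adjacent triangle
    hinge_faces_b: np.ndarray      # (E, 3) int: second adjacent triangle

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        p = self.positions
        t = self.triangles
        n = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def surface_area(self) -> float:
        return float(self.triangle_areas().sum())

    def vertex_area_share(self) -> np.ndarray:
        """Per-vertex share of the wall surface area (a third of each
        incident triangle)."""
        areas = self.triangle_areas()
        share = np.zeros(self.n)
        np.add.at(share, self.triangles.ravel(),
                  np.repeat(areas / 3.0, 3))
        return share

    def copy(self) -> "WallMesh":
        return WallMesh(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            particle_mass=self.particle_mass,
            triangles=self.triangles,
            edges=self.edges,
            rest_length=self.rest_length.copy(),
            rest_width=self.rest_width.copy(),
            hinge_faces_a=self.hinge_faces_a,
            hinge_faces_b=self.hinge_faces_b,
        )


@dataclass
class FluidState:
    """SPH fluid state. Particle count is fixed for a whole run: drying
    reduces per-particle masses, it never deletes particles."""

    positions: np.ndarray    # (N, 3) m
    velocities: np.ndarray   # (N, 3) m/s
    masses: np.ndarray       # (N,) kg, time-varying
    densities: np.ndarray    # (N,) kg/m^3
    pressures: np.ndarray    # (N,) Pa
    smoothing_length: float  # m, single global value

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "FluidState":
        return FluidState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            densities=self.densities.copy(),
            pressures=self.pressures.copy(),
            smoothing_length=self.smoothing_length,
        )


def build_wall_mesh(radius: float, subdivision_level: int,
                    total_mass: float = 0.0) -> WallMesh:
    """Icosphere wall mesh: ``10 * 4**level + 2`` vertices projected to the
    sphere of the given radius, with edge rest lengths taken from the built
    geometry and hinge adjacency for the bending force.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=radius)
    positions = np.asarray(m.vertices, dtype=float)
    triangles = np.asarray(m.faces, dtype=np.int64)

    edges = np.asarray(m.face_adjacency_edges, dtype=np.int64)
    adj = np.asarray(m.face_adjacency, dtype=np.int64)
    # A closed manifold mesh has every edge shared by exactly two triangles,
    # so the adjacency list enumerates the unique edges.
    assert edges.shape[0] == triangles.shape[0] * 3 // 2, "mesh is not closed"

    rest = np.linalg.norm(positions[edges[:, 1]] - positions[edges[:, 0]], axis=1)
    n = positions.shape[0]
    pm = total_mass / n if total_mass > 0 else 0.0
    return WallMesh(
        positions=positions,
        velocities=np.zeros_like(positions),
        particle_mass=pm,
        triangles=triangles,
        edges=edges,
        rest_length=rest,
        rest_width=rest.copy(),
        hinge_faces_a=triangles[adj[:, 0]],
        hinge_faces_b=triangles[adj[:, 1]],
    )


def fill_fluid(radius: float, spacing: float, seed: int,
               jitter: float = 0.04) -> np.ndarray:
    """Cubic-lattice packing of the cell interior.

    Lattice points strictly inside ``radius - spacing/2`` receive a small
    seeded jitter (default 4% of the spacing) that breaks lattice symmetry;
    the initial settling transient performs the actual relaxation.  If the
    spacing admits no lattice point (spacing >= 2*radius) a single particle
    at the centre is returned.
    """
    if radius <= 0 or spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    if not (0.0 <= jitter < 0.05):
        raise ValueError("jitter must lie in [0, 0.05)")
    kmax = int(np.floor(radius / spacing)) + 1
    axis = np.arange(-kmax, kmax + 1) * spacing
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    rmax = radius - spacing / 2.0 - jitter * spacing
    pts = pts[np.linalg.norm(pts, axis=1) < rmax]
    if pts.shape[0] == 0:
        return np.zeros((1, 3))
    rng = np.random.default_rng(seed)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape) * spacing
    return pts


def assign_masses(total_mass: float, n: int) -> np.ndarray:
    """Equal split of the total fluid (or wall) mass over n particles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    return np.full(n, total_mass / n)


def initial_fluid_mass_from_geometry(radius: float, rho0: float) -> float:
    """Sphere volume times reference density: regenerates the benchmark
    fluid mass (1.767e-9 kg for a 75 um cell of water-like fluid) and scales
    it to arbitrary cell sizes."""
    if radius <= 0 or rho0 <= 0:
        raise ValueError("radius and rho0 must be positive")
    return 4.0 / 3.0 * np.pi * radius**3 * rho0


def enclosed_volume(positions: np.ndarray, triangles: np.ndarray) -> float:
    """Signed volume of a closed oriented triangle mesh (sum of signed
    tetrahedra against the origin-shifted centroid); positive for outward
    orientation."""
    c = positions.mean(axis=0)
    p = positions - c
    a, b, d = p[triangles[:, 0]], p[triangles[:, 1]], p[triangles[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, d)).sum() / 6.0)
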