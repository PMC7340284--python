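"""Wall-side physics: neo-Hookean edge stiffness, edge damping, dihedral
bending and moisture-driven contraction.

The "wall element" carrying the 1-D constitutive law is the mesh edge:
lambda = l / l0 is the edge stretch, and the same edge carries the
contraction force towards its moisture-reduced target width.  Bending acts
on hinges (pairs of triangles sharing an edge) through the energy

    E_b = (k_b / 2) sum_hinges (1 - n1.n2) / (1 + n1.n2)

with n1, n2 the adjacent unit normals; the force is the exact negative
gradient of E_b, so the four-vertex stencil carries zero net force and
torque by construction.
"""

from __future__ import annotations

import numpy as np

from cellsph._accel import cross_rows, row_norms, scatter_add_vec
from cellsph.geometry import WallMesh


def stiff_force_magnitude(lam, G: float, l0, t0: float):
    """Edge force magnitude (G l0 t0 / 3)(lambda - lambda^-5): tensile for
    lambda > 1, compressive for lambda < 1."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    return G * np.asarray(l0) * t0 / 3.0 * (lam - lam**-5)


def stiff_forces(mesh: WallMesh, G: float, t0: float) -> np.ndarray:
    """Per-particle force from the edge constitutive law, equal and opposite
    on each edge's endpoints.

    The assembled edge force carries a triangular-lattice calibration
    factor lambda / sqrt(3): a network of edge tensions F produces the
    membrane tension T = sqrt(3) F / l, so the factor makes the
    triangulated wall reproduce the continuum membrane tension
    (G t0 / 3)(lambda - lambda^-5) — and with it the Young-Laplace
    equilibrium stretch — rather than an accidentally ~1.7x stiffer
    network.
    """
    pos = mesh.positions
    a, b = mesh.edges[:, 0], mesh.edges[:, 1]
    d = pos[b] - pos[a]
    l = row_norms(d)
    lam = l / mesh.rest_length
    mag = stiff_force_magnitude(lam, G, mesh.rest_length, t0) * lam / np.sqrt(3.0)
    # Positive magnitude pulls the endpoints together (tension).
    f = (mag / l)[:, None] * d
    out = np.zeros_like(pos)
    scatter_add_vec(out, a, f)
    scatter_add_vec(out, b, -f)
    return out


def damping_force(v_rel: np.ndarray, gamma: float) -> np.ndarray:
    """Linear dashpot -gamma * v_rel for one interacting wall pair."""
    return -gamma * np.asarray(v_rel, dtype=float)


def damping_forces(mesh: WallMesh, gamma: float) -> np.ndarray:
    """Edge-pair damping: edge-connected particles are the interacting
    pairs, and the full relative velocity vector is damped."""
    a, b = mesh.edges[:, 0], mesh.edges[:, 1]
    vrel = mesh.velocities[a] - mesh.velocities[b]
    f = -gamma * vrel
    out = np.zeros_like(mesh.velocities)
    scatter_add_vec(out, a, f)
    scatter_add_vec(out, b, -f)
    return out


def contraction_force_magnitude(L, L0_prime, x_over_x0: float,
                                kwc: float, a: float, b: float):
    """Wall-contraction spring k_wc [ L - L0' (1 - a b (1 - X/X0)) ].

    Positive (contractile) when the element is wider than its
    moisture-reduced target width.
    """
    target = np.asarray(L0_prime) * (1.0 - a * b * (1.0 - x_over_x0))
    return kwc * (np.asarray(L) - target)


def contraction_forces(mesh: WallMesh, x_over_x0: float, kwc: float,
                       a: float, b: float) -> np.ndarray:
    """Per-particle contraction force along each edge, pulling the edge
    width towards its dryness-dependent target."""
    pos = mesh.positions
    ea, eb = mesh.edges[:, 0], mesh.edges[:, 1]
    d = pos[eb] - pos[ea]
    l = row_norms(d)
    mag = contraction_force_magnitude(l, mesh.rest_width, x_over_x0, kwc, a, b)
    f = (mag / l)[:, None] * d
    out = np.zeros_like(pos)
    scatter_add_vec(out, ea, f)
    scatter_add_vec(out, eb, -f)
    return out


def bending_energy(positions: np.ndarray, hinge_a: np.ndarray,
                   hinge_b: np.ndarray, kb: float) -> float:
    """Total hinge bending energy (zero for a locally flat mesh)."""
    c = _hinge_cosines(positions, hinge_a, hinge_b)[0]
    return float(kb / 2.0 * np.sum((1.0 - c) / (1.0 + c)))


def _hinge_cosines(positions, hinge_a, hinge_b, strict=True):
    n1 = _tri_normals(positions, hinge_a)
    n2 = _tri_normals(positions, hinge_b)
    m1 = row_norms(n1)
    m2 = row_norms(n2)
    bad = (m1 == 0) | (m2 == 0)
    if bad.any():
        if strict:
            raise ValueError("degenerate (zero-area) triangle in bending stencil")
        m1 = np.where(bad, 1.0, m1)
        m2 = np.where(bad, 1.0, m2)
    c = np.einsum("ij,ij->i", n1, n2) / (m1 * m2)
    c = np.clip(c, -1.0 + 1e-12, 1.0)
    if not strict and bad.any():
        c = np.where(bad, 1.0, c)  # flat reading: zero force on the stencil
    return c, n1, n2, m1, m2, bad


def _tri_normals(positions, tris):
    a = positions[tris[:, 0]]
    return cross_rows(positions[tris[:, 1]] - a, positions[tris[:, 2]] - a)


def bending_forces(mesh_or_positions, hinge_a=None, hinge_b=None,
                   kb: float = 0.0, strict: bool = True,
                   degenerate_counter: list | None = None) -> np.ndarray:
    """Exact negative gradient of the hinge bending energy.

    Accepts either a :class:`WallMesh` (using its hinge tables) or raw
    position / hinge arrays, which the finite-difference oracle in the test
    suite exercises on small fixtures.  With ``strict=False`` a
    transiently degenerate (zero-area) triangle contributes no bending
    force instead of raising, and is tallied in ``degenerate_counter``;
    the edge springs re-expand such triangles within a few steps.
    """
    if isinstance(mesh_or_positions, WallMesh):
        mesh = mesh_or_positions
        positions = mesh.positions
        hinge_a = mesh.hinge_faces_a
        hinge_b = mesh.hinge_faces_b
    else:
        positions = mesh_or_positions
    c, n1, n2, m1, m2, bad = _hinge_cosines(positions, hinge_a, hinge_b,
                                            strict=strict)
    if degenerate_counter is not None:
        degenerate_counter[0] += int(bad.sum())

    # dE/dc per hinge for E = (kb/2)(1-c)/(1+c)
    dEdc = kb / 2.0 * (-2.0 / (1.0 + c) ** 2)

    nh1 = n1 / m1[:, None]
    nh2 = n2 / m2[:, None]
    # dc/dn1 and dc/dn2 (n unnormalised face normals)
    g1 = (nh2 - c[:, None] * nh1) / m1[:, None]
    g2 = (nh1 - c[:, None] * nh2) / m2[:, None]

    out = np.zeros_like(positions)
    _accumulate_normal_gradient(out, positions, hinge_a, dEdc[:, None] * g1)
    _accumulate_normal_gradient(out, positions, hinge_b, dEdc[:, None] * g2)
    return -out  # force = -grad E


def _accumulate_normal_gradient(out, positions, tris, g):
    """Chain rule through n = (b - a) x (c - a) for each triangle row:
    adds d(n . g)/dx to ``out`` at the triangle's vertices."""
    a, b, cc = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = positions[b] - positions[a]
    e2 = positions[cc] - positions[a]
    gb = cross_rows(e2, g)
    gc = cross_rows(g, e1)
    scatter_add_vec(out, b, gb)
    scatter_add_vec(out, cc, gc)
    scatter_add_vec(out, a, -(gb + gc))
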