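"""Fluid-side physics: cubic-spline kernel, equation of state, pressure and
viscous pair forces, continuity density evolution and trans-wall mass
transfer.

Sign conventions.  Pair quantities use ``v_ij = v_i - v_j`` and
``r_ij = x_i - x_j``; the kernel gradient taken at particle i is
``grad_i W = (dW/dr) * r_ij / |r_ij|``.  With these conventions the
pressure force repels particle pairs at positive pressure, the viscous
force opposes relative motion, and both are exactly antisymmetric, so the
fluid's internal forces conserve linear momentum to round-off.
"""

from __future__ import annotations

import numpy as np

from cellsph._accel import row_norms, scatter_add_scalar, scatter_add_vec

# 3-D normalisation of the M4 cubic spline whose radial profile is
# (2/3 - s^2 + s^3/2) for s < 1 and (2 - s)^3 / 6 for 1 <= s < 2:
# the unit-integral constant is 3 / (2 pi h^3).
_NORM_3D = 3.0 / (2.0 * np.pi)
# The 1-D normalisation 2/(3 pi h^3) is kept behind a compatibility flag;
# its 3-D integral is 4/9, which breaks zeroth-order SPH consistency.
_NORM_PRINTED = 2.0 / (3.0 * np.pi)


def _shape(s: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s)
    lo = s < 1.0
    hi = (s >= 1.0) & (s < 2.0)
    sl = s[lo]
    out[lo] = 2.0 / 3.0 - sl**2 + 0.5 * sl**3
    sh = s[hi]
    out[hi] = (2.0 - sh) ** 3 / 6.0
    return out


def _shape_prime(s: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s)
    lo = s < 1.0
    hi = (s >= 1.0) & (s < 2.0)
    sl = s[lo]
    out[lo] = -2.0 * sl + 1.5 * sl**2
    sh = s[hi]
    out[hi] = -0.5 * (2.0 - sh) ** 2
    return out


def kernel_value(r, h: float, printed_normalization: bool = False):
    """Cubic-spline kernel W(r, h), compactly supported on r < 2h.

    The profile is continuous and C1 at both knots; the default constant
    normalises the 3-D integral to one.
    """
    if h <= 0:
        raise ValueError("smoothing length must be positive")
    r = np.asarray(r, dtype=float)
    norm = _NORM_PRINTED if printed_normalization else _NORM_3D
    return norm / h**3 * _shape(r / h)


def kernel_derivative(r, h: float, printed_normalization: bool = False):
    """Radial derivative dW/dr; non-positive on the support."""
    if h <= 0:
        raise ValueError("smoothing length must be positive")
    r = np.asarray(r, dtype=float)
    norm = _NORM_PRINTED if printed_normalization else _NORM_3D
    return norm / h**4 * _shape_prime(r / h)


def kernel_gradient(r_vec: np.ndarray, h: float,
                    printed_normalization: bool = False) -> np.ndarray:
    """grad W = (dW/dr) r_hat, with the zero vector at the origin and
    outside the support."""
    r_vec = np.atleast_2d(np.asarray(r_vec, dtype=float))
    r = np.linalg.norm(r_vec, axis=1)
    dw = kernel_derivative(r, h, printed_normalization)
    safe = np.where(r > 0, r, 1.0)
    return (dw / safe)[:, None] * r_vec


def update_smoothing_length(D: float, D0: float, h0: float) -> float:
    """Variable smoothing length h = (D / D0) h0, following the current
    cell diameter."""
    if D <= 0 or D0 <= 0 or h0 <= 0:
        raise ValueError("diameters and h0 must be positive")
    return D / D0 * h0


def eos_pressure(rho, K: float, rho0: float, turgor_ref: float):
    """Stiffened power-law equation of state
    P = P_ref + K [ (rho / rho0)^7 - 1 ].

    ``turgor_ref`` is the turgor baseline carried by the fluid at its
    reference density; for the fresh cell it is the 200 kPa benchmark
    turgor, and the engine lowers it with moisture content as the cell
    dries (turgor loss).
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    return turgor_ref + K * ((rho / rho0) ** 7 - 1.0)


def pair_geometry(positions: np.ndarray, pairs: np.ndarray, h: float,
                  printed_normalization: bool = False):
    """Separation vectors, distances and kernel derivative for a pair list.

    Shared by the density rate and both pair forces so each step evaluates
    the kernel once per pair.
    """
    i, j = pairs[:, 0], pairs[:, 1]
    rij = positions[i] - positions[j]
    r = row_norms(rij)
    dw = kernel_derivative(r, h, printed_normalization)
    return rij, r, dw


def density_rate(masses, velocities, rho, pairs, rij, r, dw,
                 dm_dt=None) -> np.ndarray:
    """Continuity-equation density rate plus the mass-variation term:

        d rho_i / dt = sum_j m_j v_ij . grad_i W_ij + (rho_i / m_i) dm_i/dt
    """
    n = masses.shape[0]
    out = np.zeros(n)
    if pairs.shape[0]:
        i, j = pairs[:, 0], pairs[:, 1]
        vij = velocities[i] - velocities[j]
        safe = np.where(r > 0, r, 1.0)
        proj = np.einsum("ij,ij->i", vij, rij) / safe * dw  # v_ij . grad W
        scatter_add_scalar(out, i, masses[j] * proj)
        scatter_add_scalar(out, j, masses[i] * proj)  # v_ji . grad_j W is equal
    if dm_dt is not None:
        out += rho / masses * dm_dt
    return out


def pressure_forces(masses, rho, pressures, pairs, rij, r, dw) -> np.ndarray:
    """Symmetric SPH pressure force
    F_i = -m_i sum_j m_j (P_i/rho_i^2 + P_j/rho_j^2) grad_i W_ij."""
    n = masses.shape[0]
    out = np.zeros((n, 3))
    if not pairs.shape[0]:
        return out
    i, j = pairs[:, 0], pairs[:, 1]
    coef = masses[i] * masses[j] * (
        pressures[i] / rho[i] ** 2 + pressures[j] / rho[j] ** 2
    )
    safe = np.where(r > 0, r, 1.0)
    f = (-coef * dw / safe)[:, None] * rij
    scatter_add_vec(out, i, f)
    scatter_add_vec(out, j, -f)
    return out


def viscous_forces(masses, rho, velocities, mu: float,
                   pairs, rij, r, dw) -> np.ndarray:
    """Pairwise viscous (damping) force

        F_i = m_i sum_j m_j (2 mu / (rho_i rho_j)) v_ij (1/r)(dW/dr),

    which opposes relative motion because dW/dr <= 0 on the support."""
    n = masses.shape[0]
    out = np.zeros((n, 3))
    if not pairs.shape[0]:
        return out
    i, j = pairs[:, 0], pairs[:, 1]
    vij = velocities[i] - velocities[j]
    safe = np.where(r > 0, r, 1.0)
    coef = masses[i] * masses[j] * 2.0 * mu / (rho[i] * rho[j]) * dw / safe
    f = coef[:, None] * vij
    scatter_add_vec(out, i, f)
    scatter_add_vec(out, j, -f)
    return out


def mass_transfer_rate(pressures, osmotic_external: float, area: float,
                       lp: float, rho, n_fluid: int) -> np.ndarray:
    """Trans-wall mass transfer, the whole-cell flux shared equally over the
    fluid particles:

        dm_i/dt = - A_C L_p rho_i (P_i + Pi) / n_f

    Negative (water leaving) when the particle pressure exceeds minus the
    external osmotic potential.
    """
    if area <= 0 or lp <= 0 or n_fluid < 1:
        raise ValueError("area, permeability and particle count must be positive")
    pressures = np.asarray(pressures, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return -area * lp * rho * (pressures + osmotic_external) / n_fluid
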