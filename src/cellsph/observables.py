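"""Reported observables: strain, stress, area, volume, plate force,
moisture ratio and mean turgor.

Two stress readouts are reported side by side, because "stress" of a
compressed cell admits two natural estimators: the mean membrane stress
implied by the wall constitutive law, (G/3)(lambda - lambda^-5) averaged
over edges, and the nominal plate stress, top-plate reaction divided by
the initial cell cross-section pi r0^2.  Strain likewise: the mean edge
stretch minus one (the wall strain that the turgor-induced Young-Laplace
balance sets for a fresh cell), and the engineering strain of the plate
gap after first contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cellsph.geometry import WallMesh, enclosed_volume


@dataclass
class TimeSeriesRecord:
    time_us: float
    stage: str
    mean_wall_strain: float
    mean_wall_stress: float      # Pa
    nominal_plate_stress: float  # Pa
    engineering_strain: float
    surface_area: float          # m^2
    volume: float                # m^3
    plate_force: float           # N
    x_over_x0: float
    mean_fluid_pressure: float   # Pa
    plate_gap: float             # m (nan before the compression stage)


FIELDS = list(TimeSeriesRecord.__dataclass_fields__)


def cell_volume(mesh: WallMesh) -> float:
    """Enclosed volume of the closed oriented wall mesh (signed tetrahedra
    against the centroid); raises if the orientation is inverted."""
    v = enclosed_volume(mesh.positions, mesh.triangles)
    if v <= 0:
        raise ValueError("wall mesh is inverted or degenerate (volume <= 0)")
    return v


def cell_surface_area(mesh: WallMesh) -> float:
    return mesh.surface_area()


def mean_wall_strain(mesh: WallMesh) -> float:
    """Mean over edges of the stretch ratio minus one."""
    return float(np.mean(mesh.edge_lengths() / mesh.rest_length - 1.0))


def mean_wall_stress(mesh: WallMesh, G: float) -> float:
    """Mean membrane stress (G/3)(lambda - lambda^-5) over edges, the
    stress conjugate to the wall constitutive law (force per cross-section
    l0 t0)."""
    lam = mesh.edge_lengths() / mesh.rest_length
    return float(np.mean(G / 3.0 * (lam - lam**-5)))


def moisture_ratio(state) -> float:
    return state.x_over_x0


def steady_state_pressure(records: pd.DataFrame, stage: str = "drying",
                          fraction: float = 0.25) -> float:
    """Steady-state mean fluid pressure of a stage: the time average over
    the final ``fraction`` of its records.  Instantaneous SPH pressures
    carry acoustic noise of a few hundred pascal even at rest, so steady
    observables are reported time-averaged."""
    rows = records[records.stage == stage].mean_fluid_pressure
    n = max(1, int(len(rows) * fraction))
    return float(rows.iloc[-n:].mean())


def plate_observables(state) -> tuple[float, float, float]:
    """(top-plate reaction force, nominal stress, engineering strain).

    The engineering strain references the plate separation at first
    contact; pre-contact all three are zero-valued where appropriate.
    """
    p = state.params
    force = state.plate_force_top
    stress = force / (np.pi * p.cell_radius**2)
    if state.contact_height is None or state.plates is None:
        return force, stress, 0.0
    gap = state.plates.z_top - state.plates.z_bottom
    strain = max(0.0, (state.contact_height - gap) / state.contact_height)
    return force, stress, strain


class Recorder:
    """Collects one TimeSeriesRecord every ``every`` steps."""

    def __init__(self, state, every: int = 200):
        self.every = max(1, every)
        self.rows: list[TimeSeriesRecord] = []
        self.record(state)

    def __call__(self, state) -> None:
        if state.step_index % self.every == 0:
            self.record(state)

    def record(self, state) -> None:
        p = state.params
        force, nominal, eng = plate_observables(state)
        gap = (state.plates.z_top - state.plates.z_bottom
               if state.plates is not None else float("nan"))
        self.rows.append(TimeSeriesRecord(
            time_us=state.time * 1e6,
            stage=state.stage,
            mean_wall_strain=mean_wall_strain(state.wall),
            mean_wall_stress=mean_wall_stress(state.wall, p.wall_shear_modulus),
            nominal_plate_stress=nominal,
            engineering_strain=eng,
            surface_area=cell_surface_area(state.wall),
            volume=cell_volume(state.wall),
            plate_force=force,
            x_over_x0=state.x_over_x0,
            mean_fluid_pressure=float(np.mean(state.fluid.pressures)),
            plate_gap=gap,
        ))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows], columns=FIELDS)
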