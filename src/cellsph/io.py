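"""On-disk artifacts: CSV time series, extended-XYZ and legacy-VTK
snapshots (loadable by OVITO / ParaView) and HDF5 checkpoints that
round-trip the simulation state bit-exactly."""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from cellsph.geometry import FluidState, WallMesh
from cellsph.params import ModelParams


def write_timeseries(records: pd.DataFrame, path) -> Path:
    """CSV with one row per output record; column names carry the units
    (times in microseconds, SI elsewhere), '.' decimal, no separators."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    return path


def write_snapshot(state, directory, tag: str = "snapshot") -> tuple[Path, Path]:
    """Extended-XYZ of all particles plus a legacy-VTK polydata of the wall
    mesh, named ``{stage}_{step:08d}``-style under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = f"{tag}_{state.step_index:08d}"
    xyz = directory / f"{base}.xyz"
    vtk = directory / f"{base}.vtk"
    _write_extxyz(state, xyz)
    _write_vtk_wall(state.wall, vtk)
    return xyz, vtk


def _write_extxyz(state, path: Path) -> None:
    fl: FluidState = state.fluid
    wl: WallMesh = state.wall
    n = fl.n + wl.n
    wall_mass = np.full(wl.n, wl.particle_mass)
    zeros = np.zeros(wl.n)
    species = ["F"] * fl.n + ["W"] * wl.n
    pos = np.vstack([fl.positions, wl.positions]) * 1e6  # um for viewers
    vel = np.vstack([fl.velocities, wl.velocities])
    mass = np.concatenate([fl.masses, wall_mass])
    dens = np.concatenate([fl.densities, zeros])
    pres = np.concatenate([fl.pressures, zeros])
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        fh.write(
            'Properties=species:S:1:pos:R:3:velo:R:3:mass:R:1:density:R:1:'
            f'pressure:R:1 Time={state.time:.9e} Stage={state.stage} '
            f'XoverX0={state.x_over_x0:.6f}\n')
        for i in range(n):
            fh.write(
                f"{species[i]} "
                f"{pos[i,0]:.8e} {pos[i,1]:.8e} {pos[i,2]:.8e} "
                f"{vel[i,0]:.8e} {vel[i,1]:.8e} {vel[i,2]:.8e} "
                f"{mass[i]:.8e} {dens[i]:.8e} {pres[i]:.8e}\n")


def _write_vtk_wall(mesh: WallMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncell wall mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n} double\n")
        for p in mesh.positions:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        f = mesh.triangles
        fh.write(f"POLYGONS {f.shape[0]} {4 * f.shape[0]}\n")
        for t in f:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


_STATE_SCALARS = ("time", "stage", "step_index", "mass_turgid",
                  "contraction_on", "drying_frozen", "drive_effective", "freeze_step",
                  "contact_height",
                  "r0_lj", "f0a", "f0r", "r_pw", "diameter_initial",
                  "area_wall", "lj_cap_count", "escape_count")


def write_checkpoint(state, path) -> Path:
    """HDF5 container with every array and scalar needed to resume; the
    parameter set is stored as its serialized configuration document."""
    from cellsph.params import serialize_params

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        fl = f.create_group("fluid")
        for name in ("positions", "velocities", "masses", "densities",
                     "pressures"):
            fl.create_dataset(name, data=getattr(state.fluid, name))
        fl.attrs["smoothing_length"] = state.fluid.smoothing_length
        wl = f.create_group("wall")
        for name in ("positions", "velocities", "triangles", "edges",
                     "rest_length", "rest_width", "hinge_faces_a",
                     "hinge_faces_b"):
            wl.create_dataset(name, data=getattr(state.wall, name))
        wl.attrs["particle_mass"] = state.wall.particle_mass
        g = f.create_group("state")
        for name in _STATE_SCALARS:
            val = getattr(state, name)
            g.attrs[name] = "__none__" if val is None else val
        if state.plates is not None:
            pl = f.create_group("plates")
            for name in ("z_bottom", "z_top", "speed", "half_x", "half_y",
                         "r_pw", "kpw", "active"):
                pl.attrs[name] = getattr(state.plates, name)
        f.attrs["params"] = serialize_params(state.params)
    return path


def read_checkpoint(path):
    """Rebuild a SimState from :func:`write_checkpoint` output.

    The restored state reproduces the written one field-for-field; force
    caches are left empty and are re-assembled lazily on the first
    integration step.
    """
    from cellsph.engine import SimState
    from cellsph.interactions import PlateSet
    from cellsph.params import load_params

    with h5py.File(path, "r") as f:
        params = load_params(f.attrs["params"])
        fl = f["fluid"]
        fluid = FluidState(
            positions=fl["positions"][...],
            velocities=fl["velocities"][...],
            masses=fl["masses"][...],
            densities=fl["densities"][...],
            pressures=fl["pressures"][...],
            smoothing_length=float(fl.attrs["smoothing_length"]),
        )
        wl = f["wall"]
        wall = WallMesh(
            positions=wl["positions"][...],
            velocities=wl["velocities"][...],
            particle_mass=float(wl.attrs["particle_mass"]),
            triangles=wl["triangles"][...],
            edges=wl["edges"][...],
            rest_length=wl["rest_length"][...],
            rest_width=wl["rest_width"][...],
            hinge_faces_a=wl["hinge_faces_a"][...],
            hinge_faces_b=wl["hinge_faces_b"][...],
        )
        state = SimState(fluid=fluid, wall=wall, params=params)
        g = f["state"]
        for name in _STATE_SCALARS:
            val = g.attrs[name]
            if isinstance(val, str) and val == "__none__":
                val = None
            elif isinstance(val, np.generic):
                val = val.item()
            setattr(state, name, val)
        if "plates" in f:
            pl = f["plates"]
            state.plates = PlateSet(**{k: (pl.attrs[k].item()
                                           if isinstance(pl.attrs[k], np.generic)
                                           else pl.attrs[k])
                                       for k in ("z_bottom", "z_top", "speed",
                                                  "half_x", "half_y", "r_pw",
                                                  "kpw", "active")})
    return state
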