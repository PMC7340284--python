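"""Parameter sweeps: turgor pressure, compression rate, wall mechanics and
cell size, each crossed with a list of dryness levels.

Each run yields a row of summary metrics; the "late-stage slope" is the
least-squares slope of nominal plate stress against engineering strain
over the final half of the strain range reached after plate contact,
excluding the non-linear lag phase around first contact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from cellsph.engine import run_experiment
from cellsph.geometry import initial_fluid_mass_from_geometry
from cellsph.params import ModelParams

SWEEPABLE = ("turgor_initial", "plate_speed", "wall_shear_modulus",
             "wall_thickness", "cell_radius")


@dataclass
class SweepSpec:
    parameter: str
    values: list
    dryness: list = field(default_factory=lambda: [1.0])
    seeds: list = field(default_factory=lambda: [0])

    def __post_init__(self):
        if self.parameter not in SWEEPABLE:
            raise ValueError(
                f"parameter must be one of {SWEEPABLE}, got {self.parameter!r}")
        if not self.values:
            raise ValueError("value list must be non-empty")


def _configure(base: ModelParams, parameter: str, value, dryness: float,
               seed: int) -> ModelParams:
    p = dataclasses.replace(base)
    setattr(p, parameter, value)
    p.target_moisture = dryness
    p.rng_seed = seed
    if parameter == "turgor_initial":
        p.osmotic_potential = -value
    if parameter == "cell_radius":
        # fluid and wall mass scale with the cell volume
        p.fluid_mass_total = initial_fluid_mass_from_geometry(
            value, p.reference_density)
        p.wall_mass_total = 0.1 * p.fluid_mass_total
    return p


def late_stage_slope(records: pd.DataFrame) -> float:
    """Least-squares stress-strain slope over the final 50% of the strain
    range reached after plate contact (Pa per unit strain); NaN when the
    plate never engaged."""
    comp = records[records.stage == "compression"]
    strain = comp.engineering_strain.to_numpy()
    stress = comp.nominal_plate_stress.to_numpy()
    smax = strain.max() if strain.size else 0.0
    if smax <= 0:
        return float("nan")
    sel = strain >= 0.5 * smax
    if sel.sum() < 3 or np.ptp(strain[sel]) == 0:
        return float("nan")
    return float(linregress(strain[sel], stress[sel]).slope)


def detect_inertial_peaks(stress: np.ndarray, prominence: float = 0.0):
    """Local maxima of a uniformly sampled stress trace exceeding the given
    prominence; returns (indices, prominences)."""
    stress = np.asarray(stress, dtype=float)
    # always request prominences (scipy only computes them when the
    # keyword is present)
    idx, props = find_peaks(stress, prominence=max(prominence, 0.0))
    prom = props.get("prominences", np.zeros(len(idx)))
    return idx, prom


def run_sweep(spec: SweepSpec, base: ModelParams) -> pd.DataFrame:
    """One run per (value, dryness, seed) cell; failures are recorded as
    rows with an ``error`` message and the sweep continues."""
    rows = []
    for value in spec.values:
        for dryness in spec.dryness:
            for seed in spec.seeds:
                row = {"parameter": spec.parameter, "value": value,
                       "dryness": dryness, "seed": seed, "error": ""}
                try:
                    p = _configure(base, spec.parameter, value, dryness, seed)
                    res = run_experiment(p, seed=seed)
                    comp = res.records[res.records.stage == "compression"]
                    row.update(
                        late_slope=late_stage_slope(res.records),
                        min_strain=float(comp.mean_wall_strain.min()),
                        peak_force=float(comp.plate_force.max()),
                        peak_stress=float(comp.nominal_plate_stress.max()),
                        final_x=res.state.x_over_x0,
                    )
                except Exception as exc:  # noqa: BLE001 - sweep resilience
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)
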