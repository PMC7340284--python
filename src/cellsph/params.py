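"""Model parameters: loading, unit conversion, validation, serialization.

The user-facing configuration speaks the units conventional for plant-cell
micromechanics (micrometres, kilopascals, megapascals, nanoseconds); all
values are converted to SI exactly once, at load time, and every module in
the package computes in SI.  Defaults describe the benchmark apple
(Royal Gala) parenchyma cell: a 75 um radius sphere holding 1.767e-9 kg of
fluid at 200 kPa turgor, with an 18 MPa (shear) wall 6 um thick.

A handful of quantities the benchmark leaves open are exposed as explicit
fields with documented defaults: the Lennard-Jones contact ranges and
strengths (``None`` selects geometric auto-calibration at initialisation),
the plate speed and initial gap, the wall-contraction empirical constants
``contraction_a * contraction_b``, and the drying drive pressure used by the
moisture controller.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

# Multiply a configuration value in its conventional unit by this factor to get SI.
_UNIT_SCALE = {
    "cell_radius": 1e-6,              # um -> m
    "wall_shear_modulus": 1e6,        # MPa -> Pa
    "wall_thickness": 1e-6,           # um -> m
    "fluid_mass_total": 1.0,          # kg
    "wall_mass_total": 1.0,           # kg
    "wall_damping": 1.0,              # N s / m
    "fluid_viscosity": 1.0,           # Pa s
    "smoothing_length_initial": 1e-6, # um -> m
    "turgor_initial": 1e3,            # kPa -> Pa
    "osmotic_potential": 1e3,         # kPa -> Pa
    "lp_drying": 1.0,                 # m^2 s / N
    "lp_compression": 1.0,            # m^2 s / N
    "fluid_bulk_modulus": 1e6,        # MPa -> Pa
    "lj_strength_attraction": 1.0,
    "lj_strength_repulsion": 1.0,
    "bending_stiffness": 1.0,         # N m / rad
    "contraction_coefficient": 1.0,   # N / m
    "plate_stiffness": 1.0,           # N / m
    "plate_size": 1e-6,               # um -> m (each extent)
    "dt": 1e-9,                       # ns -> s
    "plate_gap_initial": 1e-6,        # um -> m
    "contact_range_plate": 1e-6,      # um -> m
    "contact_range_lj": 1e-6,         # um -> m
    "settle_time": 1e-6,              # us -> s
    "settle_max_time": 1e-6,          # us -> s
    "settle_lp_boost": 1.0,
    "drying_drive": 1e3,              # kPa -> Pa
}


@dataclass
class ModelParams:
    """Full parameter set for one cell experiment, in SI units.

    ``n_fluid``/``n_wall`` record the benchmark particle counts; together
    with ``mesh_subdivisions`` they fix the fluid:wall count ratio at any
    resolution (the actual wall count is the icosphere vertex count
    ``10 * 4**level + 2`` and the fluid count is scaled to preserve the
    ratio).  Fields defaulting to ``None`` are derived from the built
    geometry at initialisation.
    """

    cell_radius: float = 75e-6
    wall_shear_modulus: float = 18e6
    wall_thickness: float = 6e-6
    fluid_mass_total: float | None = 1.767e-9
    wall_mass_total: float = 1.767e-10
    wall_damping: float = 5e-6
    fluid_viscosity: float = 0.1
    smoothing_length_initial: float = 6.8e-6
    turgor_initial: float = 200e3
    osmotic_potential: float | None = None   # None -> -turgor_initial
    lp_drying: float = 2.5e-6
    lp_compression: float = 1.0e-12
    fluid_bulk_modulus: float = 20e6
    n_fluid: int = 3082
    n_wall: int = 2067
    lj_strength_attraction: float | None = None  # None -> auto-calibrated
    lj_strength_repulsion: float | None = None   # None -> auto-calibrated
    bending_stiffness: float = 1.0e-10
    contraction_coefficient: float = 1.0e4
    plate_stiffness: float = 1.0e3
    plate_size: tuple[float, float] = (150e-6, 150e-6)
    dt: float = 1e-9
    n_steps_drying: int = 50000
    n_steps_compression: int = 25000
    reference_density: float = 1000.0
    target_moisture: float = 1.0
    plate_speed: float = 2.0
    plate_gap_initial: float | None = None       # None -> 10% of cell height
    contact_range_plate: float | None = None     # None -> fluid lattice spacing
    contact_range_lj: float | None = None        # None -> measured wall-fluid gap
    contraction_a: float = 1.0
    contraction_b: float = 0.1
    rng_seed: int = 20200707
    output_every: int = 200
    # Discretisation / staging choices left open by the benchmark.
    mesh_subdivisions: int = 3
    settle_time: float = 4e-6
    settle_max_time: float = 30e-6
    settle_lp_boost: float = 10.0
    drying_drive: float = 300e3
    turgor_moisture_exponent: float = 1.0
    kernel_printed_normalization: bool = False

    def __post_init__(self) -> None:
        if self.osmotic_potential is None:
            self.osmotic_potential = -self.turgor_initial
        if isinstance(self.plate_size, list):
            self.plate_size = tuple(self.plate_size)

    # -- derived quantities used across modules ---------------------------

    @property
    def cell_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.cell_radius**3

    @property
    def sound_speed(self) -> float:
        """Speed of sound of the stiffened power-law equation of state at
        the reference density, c = sqrt(7 K / rho0)."""
        return math.sqrt(7.0 * self.fluid_bulk_modulus / self.reference_density)

    def wall_count_actual(self) -> int:
        return 10 * 4**self.mesh_subdivisions + 2

    def fluid_count_target(self) -> int:
        """Fluid count preserving the benchmark fluid:wall ratio at the
        configured mesh resolution."""
        return max(1, round(self.wall_count_actual() * self.n_fluid / self.n_wall))

    def fluid_spacing(self) -> float:
        """Cubic-lattice spacing giving approximately the target fluid count
        inside the cell volume."""
        return (self.cell_volume / self.fluid_count_target()) ** (1.0 / 3.0)

    def smoothing_length_effective(self) -> float:
        """Initial smoothing length at the configured resolution.

        The benchmark pairs h0 = 6.8 um with 3082 fluid particles in a 75 um
        cell (lattice spacing 8.305 um).  Other resolutions and cell sizes
        keep the same kernel support per particle spacing.
        """
        ref_spacing = (4.0 / 3.0 * math.pi * (75e-6) ** 3 / 3082) ** (1.0 / 3.0)
        return self.smoothing_length_initial * self.fluid_spacing() / ref_spacing


class ParamError(ValueError):
    """Raised for unparsable documents, unknown keys or invalid values."""


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}
_NONE_OK = {
    "osmotic_potential",
    "fluid_mass_total",
    "lj_strength_attraction",
    "lj_strength_repulsion",
    "plate_gap_initial",
    "contact_range_plate",
    "contact_range_lj",
}


def load_params(config_text: str = "", overrides: dict[str, Any] | None = None) -> ModelParams:
    """Build a :class:`ModelParams` from a YAML key-value document.

    Values are given in the configuration units (um, kPa, MPa, ns, ...);
    unknown keys are rejected.  Unset keys take the benchmark defaults.
    """
    try:
        doc = yaml.safe_load(config_text) if config_text.strip() else {}
    except yaml.YAMLError as exc:  # pragma: no cover - message path
        raise ParamError(f"configuration does not parse as YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ParamError("configuration must be a flat key-value mapping")
    if overrides:
        doc.update(overrides)

    kwargs: dict[str, Any] = {}
    for key, raw in doc.items():
        if key not in _FIELD_NAMES:
            raise ParamError(f"unknown configuration key: {key!r}")
        kwargs[key] = _to_si(key, raw)
    p = ModelParams(**kwargs)
    violations = validate_params(p)
    if violations:
        raise ParamError("invalid configuration: " + "; ".join(violations))
    return p


def _to_si(key: str, raw: Any) -> Any:
    scale = _UNIT_SCALE.get(key, 1.0)
    if raw is None or (isinstance(raw, str) and raw.lower() in ("auto", "none")):
        if key in _NONE_OK:
            return None
        raise ParamError(f"key {key!r} does not accept 'auto'")
    if key == "plate_size":
        if not (isinstance(raw, (list, tuple)) and len(raw) == 2):
            raise ParamError("plate_size must be a [length, width] pair in um")
        return (float(raw[0]) * scale, float(raw[1]) * scale)
    if key in (
        "n_fluid", "n_wall", "n_steps_drying", "n_steps_compression",
        "rng_seed", "output_every", "mesh_subdivisions",
    ):
        if float(raw) != int(raw):
            raise ParamError(f"key {key!r} must be an integer")
        return int(raw)
    if key == "kernel_printed_normalization":
        return bool(raw)
    try:
        return float(raw) * scale
    except (TypeError, ValueError) as exc:
        raise ParamError(f"key {key!r}: cannot interpret {raw!r} as a number") from exc


def serialize_params(p: ModelParams) -> str:
    """YAML document (configuration units) reproducing ``p`` under
    :func:`load_params` field-for-field."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(ModelParams):
        val = getattr(p, f.name)
        scale = _UNIT_SCALE.get(f.name, 1.0)
        if val is None:
            out[f.name] = None
        elif f.name == "plate_size":
            out[f.name] = [val[0] / scale, val[1] / scale]
        elif isinstance(val, bool) or isinstance(val, int):
            out[f.name] = val
        else:
            out[f.name] = float(val) / scale
    return yaml.safe_dump(out, sort_keys=True)


def validate_params(p: ModelParams) -> list[str]:
    """Return human-readable invariant violations (empty list if valid)."""
    v: list[str] = []

    def positive(name: str) -> None:
        val = getattr(p, name)
        if val is not None and not val > 0:
            v.append(f"{name} must be strictly positive (got {val!r})")

    for name in (
        "cell_radius", "wall_shear_modulus", "wall_thickness",
        "fluid_mass_total", "wall_mass_total", "wall_damping",
        "fluid_viscosity", "smoothing_length_initial", "lp_drying",
        "lp_compression", "fluid_bulk_modulus", "bending_stiffness",
        "settle_lp_boost",
        "contraction_coefficient", "plate_stiffness", "dt",
        "reference_density", "drying_drive", "settle_time",
        "lj_strength_attraction", "lj_strength_repulsion",
        "plate_gap_initial", "contact_range_plate", "contact_range_lj",
    ):
        positive(name)
    for name in ("n_fluid", "n_wall", "n_steps_drying", "n_steps_compression",
                 "output_every"):
        if getattr(p, name) < 1:
            v.append(f"{name} must be a positive count")
    if p.mesh_subdivisions < 0:
        v.append("mesh_subdivisions must be >= 0")
    if not (0.0 < p.target_moisture <= 1.0):
        v.append("target_moisture must lie in the half-open interval (0, 1]")
    if p.turgor_initial < 0:
        v.append("turgor_initial must be non-negative")
    if p.plate_speed < 0:
        v.append("plate_speed must be non-negative")
    if p.plate_size[0] <= 0 or p.plate_size[1] <= 0:
        v.append("plate_size extents must be strictly positive")
    if p.settle_max_time < p.settle_time:
        v.append("settle_max_time must be >= settle_time")

    # Time-step admissibility against the CFL and stiffness bounds computed
    # by the engine at the configured resolution (meaningful only once the
    # geometric and material fields are themselves valid).
    if not v and p.dt > 0:
        from cellsph.engine import stable_timestep

        bound = stable_timestep(p)
        if p.dt > bound * (1 + 1e-12):
            v.append(
                f"dt = {p.dt:.3g} s exceeds the stability bound "
                f"{bound:.3g} s (CFL / stiff-spring limit)"
            )
    return v
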