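# cellsph

A 3-D particle-based simulator for the micromechanics of a single plant
cell that is dried and then compressed between two flat plates.

Parenchyma cells (the bulk storage tissue of fruit and vegetables) behave
mechanically like thin-walled pressure vessels: the protoplast water
carries a turgor pressure `P_T` that keeps the wall in tension, and both
the turgor and the wall's solid structure change as the cell loses water.
`cellsph` models the cell fluid with weakly compressible Smoothed Particle
Hydrodynamics (SPH) and the wall with a coarse-grained (CG) triangulated
membrane, coupled through short-range contact forces, and runs the
two-stage numerical experiment — osmotic drying to a target normalised
moisture content `X/X0`, then quasi-static plate compression — reporting
stress, strain, area, volume and plate force over time.

## Model summary

Fluid particles (Table-style notation): pressure force
`F_i = -m_i Σ_j m_j (P_i/ρ_i² + P_j/ρ_j²) ∇W_ij`, Morris-type viscous
damping, a cubic-spline kernel `W` with support `2h` and variable
smoothing length `h = (D/D0) h0`, the stiffened equation of state
`P = P_ref(X) + K[(ρ/ρ0)⁷ − 1]` with `P_ref` the moisture-dependent turgor
baseline, continuity-equation density evolution with a mass-variation
term, and trans-wall mass transfer `dm_i/dt = −A_C L_p ρ_i (P_i + Π)/n_f`.
Wall particles on an icosphere mesh carry the neo-Hookean edge law
`F = (G l0 t0/3)(λ − λ⁻⁵)`, pair damping `−γ v`, dihedral bending
`E = (k_b/2) Σ (1 − n̂·n̂′)/(1 + n̂·n̂′)`, and a moisture-driven contraction
spring `k_wc [L − L0′(1 − a·b(1 − X/X0))]`.  Plates act on wall particles
through a one-sided linear contact `F = −k_pw Δx_pw`.  A fresh apple cell
(radius 75 μm, `G` = 18 MPa, `t0` = 6 μm, `P_T` = 200 kPa) settles at the
Young–Laplace wall stretch `λ*` solving `(G t0/3)(λ − λ⁻⁵) = P_T λ r/2`,
i.e. a wall strain of ≈ 0.04.

## Worked example

A fresh cell at the reduced quantitative resolution (level-3 icosphere,
stage durations preserved, time step from the stability bound; ~2
minutes on one CPU):

```python
from cellsph import presets
from cellsph.engine import run_experiment
from cellsph.sensitivity import late_stage_slope

p = presets.reduced()
p.n_steps_drying = int(round(5e-6 / p.dt))  # fresh cell: drying is inert
res = run_experiment(p, seed=1)
rec = res.records
settled = rec[rec.stage == "settle"]
comp = rec[rec.stage == "compression"]
print("settled turgor [kPa]:",
      round(settled.mean_fluid_pressure.iloc[-1] / 1e3, 1))
print("settled wall strain:", round(settled.mean_wall_strain.iloc[-1], 4))
print("min wall strain in compression:",
      round(comp.mean_wall_strain.min(), 4))
print("peak plate force [N]:", round(comp.plate_force.max(), 4))
print("late-stage stress-strain slope [MPa]:",
      round(late_stage_slope(rec) / 1e6, 2))
```

prints

```
settled turgor [kPa]: 198.5
settled wall strain: 0.0371
min wall strain in compression: 0.037
peak plate force [N]: 0.0278
late-stage stress-strain slope [MPa]: 7.8
```

The settled cell holds the 200 kPa turgor with its wall stretched to the
Young–Laplace balance (`λ* − 1 ≈ 0.040` analytically); the minimum wall
strain during compression stays at that turgor-induced stretch — the
fresh cell never drops below it; the plate force and the fitted
late-stage slope of nominal plate stress against engineering strain
quantify the compressive stiffness.  Re-running with
`target_moisture=0.5` (or 0.1) dries the cell first: the wall strain
collapses toward (and below) zero as turgor is lost, and the peak plate
force drops to roughly a third of the fresh value — dried cells are
mechanically much softer.

The same experiments are available from the shell:

```bash
cellsph make-cell --out geometry              # write mesh + packing
cellsph simulate --out run target_moisture=0.5
cellsph sweep --param turgor_initial --values 100,200,300 --dryness 1.0,0.1
```

## Layout

| module | contents |
|---|---|
| `cellsph.params` | parameter set, unit-aware loading, validation |
| `cellsph.geometry` | icosphere wall mesh, fluid lattice packing, masses |
| `cellsph.sph` | kernel, EOS, fluid pair forces, mass transfer |
| `cellsph.wall` | stiff / damping / bending / contraction forces |
| `cellsph.interactions` | neighbour search, LJ contact, plate contact |
| `cellsph.engine` | leapfrog integration, staging, moisture controller |
| `cellsph.observables`, `cellsph.io` | time series, snapshots, checkpoints |
| `cellsph.sensitivity` | parameter sweeps and trace analysis |

See `docs/methods.md` for the modelling choices, calibrations and known
limitations.
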