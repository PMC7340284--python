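# Methods

This note records the model as implemented, the calibrations behind its
defaults, and what the synthetic setup does and does not capture.  All
internal computation is in SI; the configuration accepts the units of the
table that defines the benchmark cell (μm, kPa, MPa, ns).

## The cell

A parenchyma-type cell is a fluid-filled thin-walled sphere.  Defaults
describe an apple cell: radius 75 μm, fluid mass 1.767×10⁻⁹ kg (sphere
volume × 1000 kg/m³), wall mass one tenth of that, wall shear modulus
G = 18 MPa, wall thickness t₀ = 6 μm, turgor P_T = 200 kPa, osmotic
potential Π = −P_T, fluid viscosity 0.1 Pa·s (low-Reynolds regime),
fluid bulk modulus K = 20 MPa.

### Fluid (SPH)

- Cubic-spline kernel with support 2h.  The radial profile is
  (2/3 − s² + s³/2) for s < 1 and (2 − s)³/6 for 1 ≤ s < 2; the
  normalisation is 3/(2πh³), which makes the 3-D integral exactly one
  (zeroth-order consistency).  A compatibility flag
  (`kernel_printed_normalization`) selects the 1-D constant 2/(3πh³)
  instead, whose 3-D integral is 4/9.
- Variable smoothing length h = (D/D₀)h₀ with D the wall's vertical
  extent before plate contact and the mean principal extent after.  The
  initial h₀ = 6.8 μm belongs to the benchmark resolution (3082 fluid
  particles in a 75 μm cell, lattice spacing 8.3 μm); other resolutions
  scale h₀ with the actual spacing so the neighbour count per particle is
  resolution-independent.
- Equation of state P = P_ref(X) + K[(ρ/ρ₀)⁷ − 1].  The turgor baseline
  declines linearly with normalised moisture content,
  P_ref = P_T·(X/X₀)^q with q = 1 by default
  (`turgor_moisture_exponent`; q = 0 recovers a fixed baseline).  This is
  the standard pressure–volume-curve behaviour of plant cells (turgor
  falls roughly linearly with relative water content) and is what lets a
  dried cell hold a small positive turgor at steady state; with a fixed
  200 kPa baseline and K = 20 MPa, any equilibrium would require the
  density to sit within 0.15% of ρ₀ regardless of dryness.
- Density evolves by the continuity equation plus the mass-variation term
  (ρ_i/m_i)(dm_i/dt); particle count never changes — drying removes mass
  per particle, not particles.
- Viscous force signs are fixed so the pair force opposes relative
  motion; pressure and viscous forces are exactly antisymmetric, so the
  fluid's internal forces conserve momentum to round-off.

### Wall (coarse-grained membrane)

- The wall is an icosphere: 10·4^L + 2 vertices at subdivision level L.
  Levels used: 4 ("full scale", 2562 particles), 3 (quantitative
  reduced runs, 642), 2 (trend sweeps, 162).  The fluid count preserves
  the benchmark fluid:wall ratio ≈ 1.49 at every level.
- Edges carry the 1-D neo-Hookean law F = (G l₀ t₀/3)(λ − λ⁻⁵).  The
  assembled network force includes a triangular-lattice calibration
  factor λ/√3: a lattice of edge tensions F produces membrane tension
  T = √3 F/l, so without the factor the wall is ~1.73× stiffer than the
  continuum law and the fresh cell settles at roughly half the intended
  Young–Laplace stretch (measured: strain 0.0205 instead of ~0.038).
  With it, the settled fresh wall reproduces the analytic balance
  (G t₀/3)(λ − λ⁻⁵) = P_T λ r/2 to a few percent.
- Bending is the dihedral-angle energy (k_b/2)Σ(1 − n̂·n̂′)/(1 + n̂·n̂′)
  over hinge pairs; the force is its exact analytic gradient (verified
  against finite differences), so each hinge stencil carries zero net
  force and torque.  The geometry-specific prefactor of the bending sum
  is absorbed into k_b.
- Damping acts on edge-connected pairs, −γ(v_a − v_b).
- Contraction drives each edge toward the moisture-reduced width
  L0′(1 − a·b(1 − X/X₀)), with L0′ captured at the settled fully turgid
  state.  The empirical constants default to a·b = 0.1; they are
  calibration constants for shrinkage data, and runs log a reminder to
  that effect.

### Coupling and plates

- Wall–fluid contact is a Lennard-Jones-type pair force along the pair
  axis: repulsion f0r[(r0/r)⁸ − (r0/r)⁴]/r² for r ≤ r0, clamped below
  0.1 r0 and additionally bounded by an absolute ceiling (~80× the
  calibrated contact load) so a deep penetration is recoverable within a
  few steps rather than explosive, and a short-range mirrored adhesion on
  r0 < r < 1.5 r0 with a linear taper, so the combined force is
  continuous everywhere.  A short adhesion band anchors the wall to the
  adjacent fluid layer at contact but releases it when the drying cell
  shrinks away; a full-width (2 r0) band drags the whole fluid along as
  a stuck shell under sustained tension.  The adhesion also fades
  quadratically with relative water content — wet adhesion between wall
  and water vanishes as the interface dries — which is what lets a
  90%-dried cell relax to a non-negative pressure.  The equilibrium gap
  r0 defaults to the mean wall-to-nearest-fluid distance measured at
  initialisation; the strength constants default to a geometric
  calibration at the fixed benchmark turgor (a contact compressed to
  0.9 r0 transmits 200 kPa on one fluid particle's surface patch —
  deliberately not the configured turgor, so a turgor sweep varies only
  the turgor), with the adhesion constant 8× the repulsion's, set so the
  settled fresh wall sits at the Young–Laplace stretch.  The printed
  strength constants are dimensionally inconsistent with the force law
  and, taken literally in SI, are not integrable at the nominal time
  step; explicit numeric values remain settable for anyone
  recalibrating.
- Plates are laterally finite (150×150 μm).  A wall particle within the
  contact range r_pw of a plate plane (default: the fluid lattice
  spacing) is pushed away with force k_pw(r_pw − d); the reaction is
  accumulated per plate.  The bottom plate is placed just touching the
  cell; the top plate starts above it by a configurable gap (default 10%
  of the cell height) and descends at `plate_speed` (default 2 m/s, a
  reconstruction from the benchmark's contact-time window; the
  sensitivity sweep goes to 10 m/s).

## Staging and the moisture controller

1. **Settle.**  The cell is built pre-inflated by the analytic turgid
   stretch λ* and relaxes under an osmotic servo (flux ∝ −(P_i − P_T))
   with a settle-stage permeability boost (default 10×; initialisation
   only).  The stage runs at least `settle_time` (4 μs) and extends until
   strain, mass and mean-pressure drift fall below thresholds (cap
   30 μs).  At its end the fully turgid references are captured: edge
   widths L0′, and the fluid mass X₀ (the turgid cell has taken up water
   relative to the as-built lattice, so X₀ is the settled mass).
2. **Drying.**  While X > target, mass leaves at the rate set by the
   drive pressure (floor: the configured 300 kPa; sized up if needed so
   the removal fits half the drying window at the actual turgid mass),
   tapered near the target so the final approach is quasi-static, and
   bounded by a cavitation guard: parcels whose suction exceeds half the
   drive draw water back in, so the removal transient cannot build
   runaway tension.  After the target is reached the net flux closes; a
   small influx-only term toward a 1 kPa residual turgor, capped at
   +0.8% of the target moisture, lets the dried steady state keep a
   non-negative pressure instead of drifting across zero with the last
   removal transient.  The fresh cell (target 1.0) keeps the boosted
   osmotic servo, with influx stopping if X exceeds 1.008.  In drying
   and compression a mean-free "osmotic exchange" term
   dm_i ∝ −(P_i − P̄) redistributes water between parcels at the
   drying-stage permeability: it is the per-particle pressure relaxation
   the trans-wall flux law performs around its set point, restricted to
   its zero-net part, and it is what keeps the pressure field quiet
   during removal (without it, pressure noise grows to MPa level and
   eventually collapses wall triangles).  A soft clamp bounds each
   parcel's mass to [1/3, 3]× the mean, each parcel's relative mass rate
   to 2% per step, and the net flux is re-pinned to the controller's
   intent after each bound.
3. **Compression.**  The trans-wall permeability falls to its real value
   (10⁻¹² m²s/N), the top plate descends, and observables are recorded
   every `output_every` steps.

## Time integration

Kick-drift-kick leapfrog.  The step bound is the minimum of the acoustic
CFL limit 0.25·h/c with c = √(7K/ρ₀) ≈ 374 m/s, the stiff-spring limit
√(m_w/(6k)) for the springs on one wall particle (the contraction
coefficient k_wc = 10⁴ N/m dominates; at full scale this bound is
≈1.1 ns, consistent with the nominal 1 ns step), and the explicit viscous
limit.  Presets re-derive the step at each resolution and preserve the
stage durations in simulated time (50 μs drying, 25 μs compression).
Force accumulation order is fixed and deterministic, so identical seeds
give bit-identical runs on one platform.

## Observables

Mean wall strain is the mean edge stretch minus one — for a fresh cell
its compression-stage minimum is the turgor-induced Young–Laplace
stretch.  Two stress readouts are reported side by side, since "stress"
of a compressed cell admits two natural estimators: the mean membrane
stress (G/3)(λ − λ⁻⁵) over edges, and the nominal plate stress
(top-plate reaction / πr₀²) paired with the engineering strain of the
plate gap after first contact.  Sweep summaries use the "late-stage
slope": the least-squares slope of nominal stress against engineering
strain over the final half of the strain range reached after contact,
excluding the non-linear lag phase around first touch.  Surface area and
volume come from the triangle mesh and are not conserved across stages.

## Robustness devices

Three guarded corrections keep long runs integrable, each tallied in the
run summary: transiently degenerate (zero-area) wall triangles contribute
no bending force for the affected step (the edge springs re-expand them);
a fluid particle that slips far outside the wall hull (possible through a
coarse face during the settle transient) is clamped back to the hull with
zero velocity; and the contact-force ceiling above.  None of these fire
in the quantitative level-3 runs of the benchmark configuration.

## Problem sizes

Quantitative checks (Young–Laplace equilibrium, fresh and dried strain
levels, 90%-removal stability) and the turgor-sensitivity trios run at
icosphere level 3 with ~740 fluid particles and a ~2 ns step; the
remaining trend sweeps (rate, G, size, moderate dryness) run at level 2
with a ~4 ns step.  The level-2 wall does not survive 90% moisture
removal (triangles collapse as it crumples) nor a 300 kPa settle, which
is why the turgor trios run at level 3.  Absolute particle-count
reproduction of the benchmark discretisation is not attempted (its
generation procedure is not documented, and icosphere counts cannot hit
2067 exactly).

## Known limitations of the reproduced trends

The sensitivity trends (stiffness ordering with dryness, rate-dependent
stress peaks, fresh-maximal plate force, G-insensitivity, size
robustness) reproduce at the reduced resolutions.  One does not: the
stress-strain curves of 90%-dried cells do **not** collapse across
turgor pressures here.  Because the turgid reference mass is the settled
mass, which grows with the Young-Laplace pre-stretch, cells dried to the
same relative moisture hold ~12% different absolute water across the
100-300 kPa sweep and engage the (nearly incompressible) water column at
different compression strains; the crumpled dried wall's late-stage
slope is also chaotic at these particle counts.  The corresponding test
is deliberately left failing rather than weakened.

Relatedly, the steady-state mean pressure of a 90%-dried cell is zero
rather than clearly positive: the wall contraction law with the default
a·b cannot follow the water down to 46% of the turgid radius, so the
dried fluid is a free (unconfined) droplet, and a free droplet cannot
statically hold pressure.  The measured residual is 0 ± 3 kPa (about 1%
of the fresh turgor and ~2×10⁻⁵ in relative density through the stiff
equation of state), with a seed-dependent sign; at the benchmark seed it
settles slightly positive under the hold servo.  Moderately dried cells
(X/X₀ = 0.5) remain wall-confined and hold a clearly positive residual
turgor.

## What the synthetic setup does not capture

- No cell–cell interactions, intercellular spaces or tissue-scale
  effects; measured tissue stress–strain curves are systematically
  softer than a single-cell model.
- The wall is elastic: no plasticity, no rupture, no heterogeneous G or
  t₀.
- The contraction constants a·b, the contact ranges and strengths, and
  the plate speed are calibration quantities, set by the geometric
  defaults above rather than fitted to shrinkage or indentation data.
  Quantitative dried-geometry predictions (how much a 90%-dried cell
  shrinks) follow these choices directly and should be recalibrated
  before being compared with measurements.
- No tensile-instability correction, XSPH or artificial stress terms are
  used; stability during drying rests on the osmotic-exchange damping
  described above.
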