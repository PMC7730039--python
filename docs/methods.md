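# Methods

## Model overview

The package simulates peri-implant bone healing as an iterative coupling of
three components, one iteration per healing day (35 by default):

1. a quasi-static axisymmetric Biot-poroelastic finite-element solve of the
   daily load,
2. a mechano-regulatory phenotype update driven by octahedral shear strain
   and interstitial fluid speed,
3. a stem-cell diffusion step plus property mixing and temporal smoothing.

All lengths are millimetres, stresses MPa, times seconds inside the solver
(days at the healing-loop level), and fluid speeds µm/s at the stimulus
interface. Hydraulic mobilities are tabulated in m⁴/(N·s) — intrinsic
permeability already divided by the fluid viscosity — and converted to
mm⁴/(N·s) internally (×10¹²).

## Geometry and meshing

The implant outline is a single-valued radius function r(y): a smooth
collar (neck), `n_threads` chamber units (upper flank, root, lower flank,
crest land, one pitch each), and a smooth tip section. Eagle-beak chambers
cut the lower half of each chamber to the full depth and the upper half to
60 % of it; inverse eagle-beak mirrors this. A chamber unit must close
within one pitch; violating parameter combinations raise with the violated
constraint spelled out.

The domain is a rectangle with the implant hanging from the top surface.
The healing callus is the lateral band of configurable width beyond the
thread crest, wrapping the implant flank down to the tip level; the tip
itself seats on host bone, as after a drilled osteotomy. A cortical stratum
caps the bone; the rest is cancellous. The cells-origin boundary is the
callus outer edge facing host bone (side and bottom).

Meshing uses a boundary-fitted tensor-product grid: horizontal lines snap
to every profile breakpoint and region boundary, and each row's radial
coordinates are mapped so element columns follow r(y) exactly. Region tags
are assigned by centroid containment, which is exact here because element
faces coincide with the region boundaries — per-region mesh areas equal the
region polygon areas to machine precision. Optional controls coarsen the
nearly rigid implant interior (`implant_element_factor`) and grade the
host-bone far field geometrically (`far_field_growth`); the callus band
always keeps the 0.05 mm target size. All Jacobians are checked positive.

Absolute implant dimensions are not part of the published record; the
catalog uses documented approximations (4 mm diameter, 10 mm length,
0.8 mm pitch) and every dimension is exposed in the run configuration. Only
the ordering relations between designs (flank angle A > E > F, root/crest
B < G, depth C < H, D eagle-beak, H inverse) are treated as fixed.

## Poroelastic solver

Bilinear quads carry both displacement and pore pressure (equal-order u–p);
the implant contributes elasticity only and carries no pressure unknowns.
Biot coefficient 1 and zero storativity (incompressible constituents) are
assumed, the simplest consolidation model consistent with a property table
of E, ν, k. Axisymmetric strains (ε_rr, ε_zz, ε_θθ, γ_rz) and 2πr volume
weights are used throughout; the monolithic backward-Euler operator
[[K, −Q], [−Qᵀ, −Δt·H]] is symmetric and factorized once per day.

Boundary conditions: radial fixity on the symmetry axis, axial fixity on
the base, drained (p = 0) outer domain boundary including the exposed
callus top surface, no-flux on the axis and the implant interface. The
daily load is a uniform prescribed 8 µm axial settlement of the implant top
surface (so the "average" settlement equals 8 µm), ramped over 1 s in 10
implicit steps; stimuli are evaluated at the peak-load step. The
physiological reading is one characteristic ~1 Hz biting event per day;
the ramp duration and step count are configurable.

Strains and Darcy velocities v = −k∇p are evaluated at element centroids —
the phenotype bookkeeping needs one value per element. The octahedral shear
strain treats the hoop strain as a principal strain and combines it with
the in-plane Mohr-circle pair. The fluid stimulus is the Euclidean speed
√(ν_x² + ν_y²).

### Implant–callus interface

Two modes exist. `tied` shares the mesh across the interface. The default
`coulomb_penalty` (µ = 0.3) duplicates the callus-side interface nodes and
joins the pairs with penalty springs: a stiff normal spring
(`penalty_stiffness` × tributary interface area, default 10⁵ MPa/mm) and an
elasto-slip tangential spring whose stiffness matches the adjacent callus
tissue across one element layer. The Coulomb cap |f_t| ≤ µ·max(f_n, 0) is
enforced by a damped constant-stiffness return mapping on the right-hand
side, so the factorized matrix is reused across iterations and time steps.
The tangential compliance this introduces is equivalent to one extra
element layer of interface tissue; the normal force entering the friction
cap is the effective (solid-skeleton) traction, the appropriate quantity
for frictional contact in a saturated medium. Friction here uses total
relative displacement (deformation-theory slip), adequate for the
monotonic, proportional daily ramp.

### Verification oracles

- Uniaxial confined patch test: exact to machine precision.
- Terzaghi consolidation column (step load, top drained): pore-pressure
  profiles within 2 % relative L2 of the series solution at Tv = 0.1 and
  0.5; centroid Darcy speeds within 3 %.
- Lamé pressurized thick-walled cylinder: radial displacement within 1 %,
  observed L2 convergence rate 2.0 under mesh halving.
- Half-space erfc profile for the diffusion kernel, within 2 %.

`osseoheal verify` runs these from the command line.

## Stem-cell diffusion and calibration

Concentration (fraction of n_max = 1) diffuses over the callus sub-mesh
only, with the cells-origin boundary held at full concentration and
no-flux elsewhere (implant surface, exposed top). Lumped-mass backward
Euler in one-day steps preserves the discrete maximum principle up to the
small Gibbs undershoot of non-M-matrix bilinear quads at the sharp day-1
front; violations beyond 1 % of n_max raise. The initial condition is
n = 0 (granulation before cell invasion). "Random anisotropic diffusion"
in the modeling tradition this follows is implemented as deterministic
isotropic diffusion; no stochastic scheme is involved.

`calibrate_diffusivity` bisects (to 1 % relative) for the smallest D whose
minimum callus concentration reaches the saturation threshold — 0.99·n_max,
since exactly 1 is only reached asymptotically — at the 35-day horizon. On
the reference geometry this gives D ≈ 0.012 mm²/day and a saturation day of
exactly 35; the calibrated D moves by < 1 % under mesh halving.

## Healing loop

Within a day the order of operations is: solve → classify (for the next
day) → diffuse → mix → smooth. The published procedure does not pin this
order down; it is a documented choice, not asserted as the original. Day 1
uses pure granulation properties in the callus. Elements classified as
resorption are assigned granulation properties (the softest state; the
property table has no resorption row) and counted as non-bone in
morphometry. S = 0 (possible at zero load) classifies as resorption.
Phenotype is decided per element from centroid stimuli with no spatial
smoothing. Temporal smoothing averages the current mixed value with up to
nine previous smoothed values; for early iterations the divisor is the
actual number of summed terms. The pipeline contains no randomness:
identical configurations produce identical histories.

## Morphometry

BIC counts the ROI interface length (upper/lower flanks and roots of all
threads; crest and collar faces and the tip excluded) whose adjacent callus
element is mature or immature bone. BA counts the bone fraction of the
inter-thread chamber area. Both use in-plane element lengths/areas —
mimicking a 2D histology section — with a volume-weighting (2πr) switch.
Immature and mature bone are pooled for the headline values and reported
separately, since immature-dominated contact overstates mechanical
competence (immature bone is six times softer).

## Reference geometry and scaled analogs

`single_chamber` is a compact reference: 2 mm-diameter implant, a 1 mm
smooth neck passing through a 0.8 mm cortical plate, one trapezoidal
chamber (depth 0.3 mm, 60° flanks), a short tip, 0.35 mm callus band, in a
2×3 mm bone section (~1950 elements at the 0.05 mm mesh). The design
regression uses scaled-down analogs of the catalog designs: three threads,
2 mm diameter, identical mesh density (~3000 elements), so five 35-day runs
finish in under two minutes. Problem sizes were chosen so the full suite
runs on a laptop-class single core.

## What the synthetic fixtures do and do not show

The generator produces geometry, not data: all "observations" are model
outputs. Passing tests demonstrate that the implemented equations,
thresholds, calibration and scoring behave exactly as specified and that
the numerical kernels converge to the right continuum solutions. They do
not validate the biology against new histology, and the scaled-down
geometries shift absolute BIC/BA and stimulus levels; only ordering
conclusions between designs transfer across scales.

A known consequence: with the standard 8 µm head settlement on desk-scale
domains, the minimum stimulus over the callus stays at S ≈ 0.02–0.05 —
above the 0.010 resorption boundary — so load-driven crestal resorption
does not occur in the compact runs (it requires the quiet far field of a
full-size, multi-thread geometry). The resorption pathway itself is
exercised by the zero-load and classification tests. At these scales the
model predicts complete chamber coverage (BIC/BA near 100 %) by day 35;
the informative outputs are the orderings between designs and the
mature/immature splits.

## Known limitations

- 2D axisymmetry: only vertical loading; no lateral or oblique bites.
- Linear kinematics; no large sliding, no gap opening beyond the penalty
  regularization; no cyclic micromotion within a day.
- Single cell species; no proliferation, chemotaxis or angiogenesis.
- Equal-order u–p elements rely on resolved boundary layers rather than
  inf-sup stabilization; very early-time consolidation on coarse meshes can
  oscillate.
- The histomorphometry ROI follows one fixed definition (flanks + roots);
  crest faces are excluded by construction.
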