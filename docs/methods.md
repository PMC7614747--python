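# Methods

## Scope and strategy

The package analyses RF exposure of a term neonate inside a 7 T (297 MHz)
adult head transmit coil.  Two stages are deliberately decoupled from any
electromagnetic field solver:

1. **Dosimetry bookkeeping** — given |E| and B1+ grids on a voxel model,
   compute pointwise, region-averaged and 10 g mass-averaged SAR, and
   normalize them to input power, net-forward power, absorbed power, or
   achieved mean B1+² in a central axial slice.
2. **Thermal response** — solve the Pennes bioheat equation on the same
   grid with a convective surface boundary, optional insulation, and a
   finite blood pool.

Full-wave simulation of the birdcage coil is not attempted.  Exposure
fields are either imported (HDF5) or produced by a parametric surrogate;
the published per-model EM summary values ship as a fixture so the derived
compliance arithmetic (allowed power, exposure ratios, B1 derating) is
recomputed through the package's own normalization and limit operations.

## Synthetic phantom

Real segmented neonate models are MRI-derived and unavailable from text,
so the generator builds a stand-in from nested ellipsoids on a
96×96×144 grid of 2 mm voxels: a spherical head (skin/fat/skull/CSF/brain
shells) whose volume is fixed at 1030 mL, an ellipsoidal torso containing
heart wall + blood core, lungs, liver, stomach, a bony spine in a
connective-tissue sheath and sternum cartilage, four limb ellipsoids, and
a small hand resting near the face (a posture common in scanned infants
that creates a superficial exposure feature).  Thirteen tissue classes are
used.  A single scale factor on the torso and limbs is found by bisection
so the total mass (Σ ρ·ΔV over tissue) hits 3.50 kg within 0.2 %; the head
is never rescaled.  The seed jitters interior organ positions by ≤0.5 mm;
a fixed seed reproduces the phantom bit-exactly.

Coordinate convention, used everywhere: 0-based indices, axes
(x = left–right, y = anterior–posterior, z = inferior–superior), world
coordinates = index × voxel size from the grid corner, voxel centers at
(index + ½) × voxel size.  The face points toward −y.

What the phantom does **not** emulate: real anatomy (tissue topology,
folded limbs, airways), partial-volume boundaries, and realistic organ
masses beyond density-weighted bulk.  Tests passing on this phantom
validate the *operations* (averaging, normalization, heat transport), not
anatomical temperature maps; absolute temperatures and crossing times on
the synthetic phantom are illustrative, not predictions for a real infant
(see Limitations).

## Tissue properties

`tissues_adult.csv` carries per-tissue permittivity and conductivity at
297 and 127 MHz plus density, thermal conductivity, specific heat,
perfusion (mL·min⁻¹·kg⁻¹) and metabolic rate, with a provenance string per
row; values are representative adult-database numbers and the file is
meant to be edited.  Age adjustment multiplies εr and σ by per-tissue
newborn/adult ratios.  The shipped `scaling_neonate.csv` is a clearly
labeled synthetic default built on the water-content argument (ratios ≥ 1,
largest for low-water tissues such as fat and bone, unity for CSF);
authoritative ratios should be supplied for publication-grade use.
Thermal properties and density are never scaled: higher neonatal water
content would raise conductivity and heat capacity, so adult values are
the conservative (hotter) choice.  Lookups require the requested frequency
to lie within 10 % of a stored one; there is no dispersion model.

Perfusion enters the bioheat equation as a volumetric blood mass exchange
rate `W_b = ρ_tissue · w · ρ_blood · 1e−6/60` (kg blood·m⁻³·s⁻¹), so the
heat term is `W_b·c_b·(T_blood − T)` in W/m³.

## SAR

* RMS convention: `SAR = σ|E|²/ρ`, no factor ½.  All values are 100 % duty
  cycle; duty-cycle averaging is the caller's concern.
* Region averages are mass-weighted (`Σ SAR·ρ·ΔV / Σ ρ·ΔV`).
* **psSAR10g**: for every tissue voxel a centered cube grows one shell at
  a time; the first shell that pushes the enclosed tissue mass past 10 g
  is weighted fractionally so the mass is exact, and the average uses
  deposited power / 10 g.  Air and blanket contribute zero mass and zero
  SAR inside the cube.  A voxel whose cube would have to cross the grid
  boundary before reaching 10 g is *invalid* and excluded from the peak.
  Ties break to the lowest linear index.  The implementation uses 3-D
  summed-area tables; its correctness standard is exact agreement (1e−9
  relative) with an exhaustive per-voxel search, enforced in the tests.
  Cubes are cubes in voxel counts; on anisotropic grids they are boxes.
* The mean B1+ for per-B1+² normalization averages |B1+| over tissue
  voxels only in the model's reference axial slice (air B1 is meaningless
  for exposure normalization).  In the position-shift experiment the
  reference slice translates with the model, emulating imaging of the same
  anatomy at a different position; shifts are quantized to whole voxels
  with the residual logged, and rows whose shift clips >20 % of tissue are
  flagged.

### Surrogate exposure fields

The surrogate emulates the gross structure of a head-coil exposure, not
its detail: |E| ∝ (cylindrical radius / grid radius) × a Gaussian axial
envelope (σ_z = 100 mm) centered on the reference slice — E vanishes on
the coil axis and falls off away from the coil, as in a birdcage — with an
optional superficial Gaussian hotspot (default at the back of the neck).
The pattern is scaled so integrated absorbed power equals
`absorbed_fraction × P_in` (default 0.59); reflected power is a parameter
(default 0.11) and the remainder is booked as radiated, closing the budget
exactly.  B1+ is a mildly center-weighted profile scaled so the mean slice
|B1+| equals `b1_efficiency·√P_in`; defaults 0.53 µT/√W with age-adjusted
properties and 0.61 µT/√W with adult properties, following the published
efficiencies, which is what makes per-B1+² SAR rise when neonatal
dielectric properties are selected.  The defaults reproduce the study's
power-budget structure; on the synthetic phantom they yield head-average
0.32, whole-body 0.17 and psSAR10g 1.13 W/kg/W, with the global 10 g peak
in the hand near the face.

## Bioheat solver

Finite-volume discretization on the voxel grid; air carries no
temperature and acts only through the boundary:

* Face conductance between adjacent domain voxels: harmonic mean of the
  two conductivities times face area over spacing (exact for layered
  media).
* Exterior faces (tissue–air, blanket–air, grid boundary): Robin loss with
  the surface coefficient *h* in **series with the half-voxel conduction**
  `1/(1/h + dx/2k)`, so the convective flux applies at the surface rather
  than the cell center; this keeps the discrete steady slab profile within
  ~1e−4 of the closed form instead of O(dx) off.  One *h* for the whole
  exterior, insulated or not.
* Explicit forward Euler with automatic stable step
  `dt = 0.9·min C/(ΣG + R + W_b c_b ΔV)` (≈1.8 s on the 2 mm phantom); a
  non-finite or >100 °C temperature aborts with a diagnostic.
* Blood pool: `V_b ρ_b c_b dT_blood/dt = Σ W_b c_b (T − T_blood) ΔV`,
  integrated with the same step, exchange evaluated at current
  temperatures (operator split).  Defaults: V_b = 324 mL, ρ_b = 1050,
  c_b = 3617.  With the pool disabled T_blood is constant.
* Temperature-dependent perfusion (adult mode only; neonatal
  thermoregulation is immature, so neonate runs keep perfusion constant —
  conservative): per-tissue multiplier 1 below 39 °C, linear to a maximum
  at 45 °C, constant above.  The ramp maxima (skin 10, muscle 10, fat 5,
  brain 2) are configurable placeholders for the literature values, which
  this package does not fix.
* Core temperature = mass-weighted mean over the 1-voxel-eroded heart+brain
  mask (arithmetic mean available); a compartment eroding to nothing falls
  back to its un-eroded voxels.

### Protocol and calibration

Every simulation starts from the conditioning run: uniform 37 °C tissue,
22 °C ambient, h = 8 W m⁻²K⁻¹, fixed core, 60 min — activating the blood
pool from the unphysical uniform state gives unreliable trajectories.  On
the packaged phantom this ends with a maximum of 37.6 °C (heart) and mean
skin 34.4 °C.  Exposure runs then use h = 11 W m⁻²K⁻¹.

The blanket is voxelized as a tissue-like wool layer (k = 0.04 W/m/K,
ρ = 150, c = 1300, zero perfusion and metabolism) grown as a
Euclidean-distance shell over the skin, leaving a 45 mm-radius face
aperture open.  Its default thickness (6 mm) is the package's calibration:
with h = 11, dynamic core and no RF, the insulated phantom's core is
near-stationary (+0.13 °C/h) while the uninsulated phantom cools toward
hypothermia (≈ −2.9 °C/h) — the qualitative regime the protocol requires.
Absolute drift rates depend strongly on the phantom's compact geometry
(lower surface-to-volume ratio than a real supine neonate), so crossing
times on the synthetic phantom occur earlier than published anatomical
results; the monotone structure (insulation stabilizes; lower h advances
the 0.5 °C crossing) is the tested claim.

## Compliance

Limits are plain numbers (defaults: head 3.2 W/kg, psSAR10g 10 W/kg, core
rise 0.5 °C, absolute 39 °C; whole-body optional) — no operating-mode
taxonomy.  Allowed power is `min(limit / SAR-per-watt)` over the SAR
limits.  Thermal crossings interpolate linearly between samples; the
core-rise baseline defaults to the core temperature at RF onset, and both
that and a fixed-37 °C baseline can be evaluated since the guideline is
ambiguous for an already-cooling neonate.  The h-sweep reuses one
equilibration state across h values (the conditioning protocol pins its
own h), isolating exposure-phase sensitivity.

## Numerical choices and degenerate inputs

* Mass calibration tolerance 0.2 % (validation rejects >5 %); head volume
  tolerance 10 %.
* Budget closure tolerance 1 % everywhere a power budget is constructed
  or imported.
* Zero-thickness blanket is the identity; thickness below one voxel is an
  error (it cannot be voxelized).
* Shifts larger than the grid, empty region masks, zero densities in
  tissue, unknown tissues and >10 % frequency mismatches are explicit
  errors naming the offending item.
* Test problem sizes: solver verification uses 8³–64³ grids; the protocol
  demonstration runs the packaged phantom (96×96×144 at 2 mm, ~0.4 M
  tissue voxels) through the full 60 + 60 min protocol.

## Known limitations

* No electromagnetic solver: absolute SAR on the synthetic phantom is set
  by the surrogate's absorbed-power fraction, not by coil physics; only
  normalized structure is meaningful there.  The published-fixture route
  carries the physics for the worked examples.
* Heat loss is a single lumped h (no separate radiative, convective or
  evaporative channels, no humidity); no active thermoregulation,
  incubator or radiant-warmer models.
* The psSAR10g cube is an IEC-style simplification, not the
  surface-conforming region growth of commercial solvers; agreement with
  any particular solver's per-voxel values is not claimed.
* Dielectric ratios and the perfusion ramp are labeled defaults awaiting
  authoritative values.
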