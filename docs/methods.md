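# Methods

## Scope and model

`awplan` plans rigid poses of a curvilinear ultrasound transducer on the
body surface so that one or more target points are imaged through the best
available acoustic window.  The planner is purely preoperative: it consumes
a CT volume (and optionally an organ segmentation on the same grid) and
produces poses; execution, patient registration, live imaging and 3D
compounding are out of scope.

The model chain is:

1. **Surface**: the body is segmented from CT (largest connected component
   above a skin threshold, default −300 HU, morphologically closed), and
   its 0.5 iso-surface extracted by marching cubes on a Gaussian-smoothed
   (σ = 1 voxel) mask.  Vertex normals come from the smoothed-field
   gradient, sign-fixed outward.  Vertices are subsampled by 3D grid
   binning at pitch `1/sqrt(density)`; the default density 0.25 points/mm²
   is a configuration knob, not a physically derived value, and planning
   cost is linear in the number of surface points.  Binning happens in
   grid-attached coordinates so that rigidly moving the volume moves the
   selected points with it.
2. **Hard constraints**: a candidate surface point must have the target
   within the penetration depth d_y, and the probe axis (aimed at the
   target) within α of the inward surface normal.  α = 30° by default —
   the tilt a probe can sustain while staying acoustically coupled.  The
   tilt test is implemented as ⟨d_a, −n_s⟩ ≥ cos α with outward normals
   n_s.
3. **Transmission**: HU maps affinely to an attenuation proxy
   μ = max(1 + HU/1000, ε), ε = 10⁻³.  μ is proportional to tissue density
   and, under the constant-speed-of-sound assumption, stands in for
   acoustic impedance; only ratios of μ enter, so the overall scale cancels
   (this is asserted by a property test).  The floor makes tissue/air
   interfaces reflect near-totally and keeps denominators positive.
   A ray accumulates `t = exp(−Σ_j r_j²)` over the interfaces j it
   crosses, `r_j = |μ_b − μ_a|/(μ_a + μ_b)`, which agrees with the
   single-interface transmission coefficient `1 − r²` to O(r⁴).  The
   per-pose quality t̄ is the mean of the log-compressed profile
   `t̂ = log(1 + νt)/log(1 + ν)` (ν = 0.5) over all scan-lines and depth
   samples; compression is applied to the cumulative transmission at every
   depth sample, since the depth integral runs over t̂.
4. **Search**: exhaustive evaluation of t̄ over candidates × a roll grid
   (default 5°, domain [0°, 180°) by the π-periodicity of the image
   plane), two-staged as best-roll-per-candidate then best candidate.
   With a full grid the two stages equal the joint argmax, and the test
   suite holds the planner to *exact* agreement with brute-force
   enumeration.  Convexity of t̄ in roll is not assumed.  Ties break
   deterministically: lowest surface index, then smallest roll.  Multi-view
   plans share one base point admissible for all targets; given the base
   point the product objective factorises, so rolls are optimised per
   target and bases compared on Σ log t̄.

## Numerical choices

**Interface detection (run coalescing).**  A discrete sum of per-step
reflection ratios is ill-posed at sharp interfaces: trilinear interpolation
smears a jump over one voxel, so halving the step would split one interface
of ratio r into two of ratio ≈ r/2, contributing r²/2 instead of r².  The
integrator therefore coalesces consecutive same-direction changes of the
sampled μ profile into a single transition scored from its endpoint values.
One sharp interface then contributes exactly r² at any step size (verified
for steps 0.25/0.5/1.0 mm against the closed form exp(−1/9) on a
0 → 1000 HU slab), and a smooth monotone gradient is treated as one
interface — the physically sensible limit, since an adiabatic impedance
taper reflects little; the formula still charges it r² of its total jump,
which is conservative.  Reversals and flat steps close the active
transition, so separated interfaces accumulate independently.  An
in-progress transition contributes its partial jump, keeping t̂
non-increasing in depth.

**Probe coupling.**  The lateral elements of a curved array stand off the
skin (up to ~7 mm for a 40 mm radius, 70° aperture), so their rays begin in
air.  Charging that air would subtract a near-constant from every pose and
drown the anatomy signal in surface-curvature noise, so leading sub-tissue
samples (μ < 0.9, i.e. < −100 HU) are forward-filled from the first tissue
sample — the standoff is assumed filled with coupling gel — but only
within 12 mm of the ray origin.  A ray still in air beyond that standoff is
treated as insonifying from gel (μ = 1) into air and pays the near-total
reflection at the transducer face.  Without this last rule, rays that miss
the body entirely would cross no interface and score a perfect 1.0, and the
optimiser would actively seek poses with half the fan in air.

**Sampling.**  CT and μ are sampled trilinearly; organ labels
nearest-neighbour.  Points outside the volume read as air (−1024 HU /
μ = ε): rays legitimately start at the skin and fans may clip the volume,
and air is the conservative value.  The default ray step is half the
smallest voxel spacing.  Pose evaluation is vectorised over chunks of
(pose × scan-line × depth) samples; the batched and single-pose paths are
cross-checked to 10⁻¹².

**Evaluation.**  Planned poses are scored on the CT plane spanned by the
lateral and axial axes through the base point, restricted to the
curvilinear fan (radial distance in [R, R + d_y] from the array's centre of
curvature, within the aperture).  `r_ct` is the in-fan fraction outside
[β₁, β₂] = [−100, 150] HU; `r_seg` the in-fan fraction inside the organ
label.  Ratios are computed over fan pixels only — rectangle background
would dilute both.  Default slice pixel spacing is the smallest CT spacing,
to avoid aliasing thin ribs.

## Synthetic phantom

The generator emulates the one structure the planner must exploit: ribs
with intercostal gaps between the skin and a target organ.  It builds an
air background (−1000 HU), a soft-tissue elliptic cylinder (40 HU), a
liver-like ellipsoid label (60 HU) and bone-density rib arcs (900 HU, 4 mm
radius, 14 mm gaps) inset from the anterior surface, plus Gaussian noise
(σ = 10 HU); targets are drawn uniformly from the organ after a 2-voxel
erosion so coverage is unambiguous.  Everything is determined by one seed.
The palette places soft tissue inside the [−100, 150] HU band with bone far
above it, so the evaluation thresholds act as intended.

What the phantom does *not* reproduce: realistic CT texture and artifacts,
organ heterogeneity, bowel gas, lungs, respiratory deformation, and a torso
much larger than the probe fan.  Tests passing on the phantom therefore
show that the planner discovers geometric acoustic windows under the stated
transmission model — not that clinical image quality improves on patient
data.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| d_y | 140 mm | penetration depth (4DC7-3/40-class curvilinear probe) |
| array radius / aperture | 40 mm / 70° | curvilinear fan geometry |
| N_el | 64 | planning scan-lines (speed/fidelity knob) |
| α | 30° | maximum probe-to-normal tilt |
| roll grid | 5° over [0°, 180°) | orientation discretisation |
| ν | 0.5 | log-compression factor |
| ε | 10⁻³ | μ floor (air) |
| β₁, β₂ | −100, 150 HU | soft-tissue band for r_ct |
| skin threshold | −300 HU | body mask |
| surface density | 0.25 /mm² | candidate discretisation |

## Study problem sizes

The packaged comparison study (`awplan.study.rib_phantom_study`, also run
by `scripts/acceptance.py`) uses desk-scale sizes chosen as the package's
own defaults for a laptop-class run: the default 96×96×64 phantom at 2 mm
spacing, 25 organ targets, 16 scan-lines, a 15° roll grid, 2 mm ray step
and 0.02 surface points/mm².  Exhaustive-oracle checks run on a smaller
64×64×48 phantom with ≤ 500 surface points.  Coarser than clinical
planning, these sizes preserve the rib/gap structure the comparison is
about.

## Known limitations

- Straight rays, constant speed of sound: no refraction, no
  frequency-dependent absorption, no scattering or speckle; μ is a density
  proxy, so soft-tissue impedance contrasts (e.g. liver vs fat) are only
  approximate and bone contrast is understated relative to physical
  impedances.
- The roll grid discretises orientation; the naive baseline's
  normal-derived roll is generally off-grid, so the planner's dominance
  over the baseline on t̄ is checked empirically rather than guaranteed.
- Multi-view trajectories share a single base point; sweeps with moving
  base points are not modelled.
- Organ labels must be co-registered with the CT grid; no resampling or
  registration is performed.
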