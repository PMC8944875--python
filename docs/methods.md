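# Methods

## Model structure and assumptions

The distal forelimb is a driven multibody chain. The elbow, carpus,
fetlock and distal interphalangeal (coffin) joints are hinges on the
sagittal plane (all hinge axes +y in a right-handed frame with +x the
direction of motion and +z up); the proximal–middle phalanx junction and
the C2–C3–C4 distal carpal row are fused, and the distal row is fixed to
the metacarpus. Humerus and ulna are carried along with the prescribed
radius and have no independent dynamics. Only the three proximal carpal
bones (Cr, Ci, Cu) are dynamic — free 6-DOF rigid bodies squeezed between
the radius above and the distal row below. This reproduces the structure
of an inverse-dynamics-driven joint model: measured gross kinematics in,
intra-articular forces out, with no muscle–tendon actuation. The digital
flexor/extensor tendons are deliberately absent, so the computed carpal
loads are a lower bound on the in-vivo loads.

The carpus hinge is placed between the radius and the distal row; whether
the dominant physiological axis is antebrachiocarpal or midcarpal is not
resolved here — the intercalated free bones distribute the rotation.

### Geometry

Real articular surfaces are replaced by parametric stand-ins: each radius
facet (medial/radial, intermediate, ulnar) is a circular-arc part-cylinder
patch about the carpus axis (radius 35 mm, 120° span; widths 30/25/15 mm
so that candidate contact area is ordered medial > intermediate > ulnar),
and each opposing carpal facet is its exact outward offset by the total
cartilage gap (default 1.0 mm), so at the reference full-extension pose
the minimum bone separation equals the gap by construction. The
synthetic Cr is intact by construction; no fracture-reconstruction step
exists. Bone density is 1590 kg/m³; segment inertias come from the
divergence-theorem mass properties of closed meshes (trunk cylinder,
carpal boxes) or from analytic radius-of-gyration values for the shaft
segments, whose inertia never enters the free-body dynamics.

### Force elements

*Ligaments.* Each branch is a tension-only spring with a quadratic toe
(ε ≤ ε_t = 0.03) blending C¹-continuously into a linear region,
F = k(ε − ε_t/2), plus viscous damping applied only while taut and
lengthening (compressive damping in a tension-only element would be
nonphysical). Stiffnesses per unit strain (collaterals 3·10⁴ N,
retinacular branches 1.5·10³ N, palmar carpal ligament 10⁵ N) are
adapted-from-literature defaults, overridable per branch. Slack lengths
are tuned so every branch carries exactly the reference strain (default
0) at the resting pose; `simulate_stride` re-tunes them at the limb
posture of stride start, the code's equivalent of tuning by preliminary
simulation. Attachments are kept close to the flexion axis because a
straight-line element cannot wrap: distant dorsal anchors would strain
tens of percent in deep swing flexion and inject spurious kilonewton
forces.

*Bushings.* The intercarpal ligaments and joint capsule are lumped into
diagonal linear six-component bushings (force/torque proportional to
relative displacement/velocity in the bushing frame; no
translation–rotation coupling, since no evidence supports a particular
coupling structure). Each carpal bone is suspended by a stiff "seat"
bushing from the distal row (K_t = 2·10⁷ N/m — the midcarpal
articulation through which stance load passes), a soft capsular bushing
from the radius (K_t = 5·10⁵ N/m, K_r = 80 N·m/rad, which keeps each
bone angularly tracking the radius facet it articulates with), and
intercarpal couplings Cr–Ci and Ci–Cu. The row-bushing frame sits at the
carpal COM plane: anchoring it distally would add a lever-arm rotational
stiffness k·r² ≈ 10⁴ N·m/rad on a ~3·10⁻⁶ kg·m² inertia and push the
explicit rotational dynamics against its stability limit. All damping
coefficients are chosen to keep c·dt/m and c·dt/I well below the
explicit-integration bound of 2.

### Contact

The interpenetration function references the cartilage: onset is at bone
separation equal to the local C.Th (scalar or per-face map), and
δ = C.Th − separation. The normal force is F = k_c δ^e with e = 1.5
(Hertz-like) plus damping that ramps cubically from 0 at δ = 0 to c_max
at δ = d_ramp (so the force is continuous at onset), clamped at zero —
no adhesion. Per-facet stiffness is calibrated as
k_c = E·A / C.Th^e (cartilage aggregate modulus E = 10 MPa, facet area
A), i.e. the force at full cartilage compression is E·A; at e = 1 this
reduces to the simpler E·A/C.Th form. Articular pairs are frictionless;
the hoof–ground contact adds velocity-regularised Coulomb friction
(μ = 0.55 — the dirt-track value is not known; all ground parameters are
config). In the stride loop, penetration against the parametric facets is
evaluated analytically (distance to the opposing cylinder axis) at every
radius-facet face centroid; the generic mesh path
(`contact.detect_penetration`) uses an exhaustive vectorised
point–triangle query and agrees with a brute-force oracle on small
meshes. The CoC is the force-weighted centroid of active contact points,
projected radially onto the radius facet, and is also reported as a
trochlear angle (positive dorsal).

### Drive reconstruction

`kinematics.build_drive` lays PCHIP (C¹, monotonicity-preserving) splines
through phase landmarks: hoof forward speed decelerates to exactly zero
at the impact landmark (18 ms) and stays zero through stance; the hoof
height reaches the ground at impact and sinks ~2 mm into the compliant
track; trunk speed peaks at exactly the scenario speed (14 m/s); limb
inclination-to-ground bottoms out at exactly the scenario lean (56°) near
mid-stance; carpal angle passes through the impact/extension/flexion
landmarks with a flexion dip under the stance load and full flexion
(~120°) in mid-swing. The carpal angle landmarks are not available as measurements;
the shipped values (impact 182°, max extension 183°, max flexion 120°)
are documented placeholders consistent with galloping carpal kinematics,
using the convention 180° = straight limb, decreasing with flexion, with
mild hyperextension under load.

Besides the gross series the drive carries the radio-carpal
*micro-motion* — the package's reconstruction of how the measured stride
loads the joint, since a position-driven chain transmits load only
through prescribed relative displacement:

- an axial approach (squeeze) of the radius toward the distal row, with a
  stance bump (peak 0.87 mm) and a smaller full-flexion bump in swing
  (0.55 of the stance amplitude) — the compression of the cartilage
  stack under limb load;
- a loaded dorso-palmar shear (+0.8 mm dorsal at early stance, −1.2 mm
  palmar at mid-stance), the arthrokinematic palmar glide of the loaded,
  flexing joint;
- a frontal (medial) tilt proportional to the load bump (4 mrad peak),
  representing the medial load shift of the leaning limb.

The squeeze amplitude is the one deliberately calibrated constant of the
scenario: it was set once so that the shipped defaults produce a
radio-carpal force peak in the ≈7 kN range with the medial > intermediate
> ulnar ordering, the same role preliminary-simulation tuning plays when
a commercial solver is fitted to measured kinematics. Everything else
follows from the documented scenario constants.

### Integration and verification instruments

Kick-drift-kick (leapfrog) velocity Verlet at dt = 10 µs, one force
evaluation per step, with a velocity predictor for the damping terms and
quaternion renormalisation every step. The scheme is exact on free fall
and symplectic on the stiff penalty springs (bounded energy oscillation,
no drift); the stiffest mode in the shipped model has ω·dt ≈ 0.2.
Events use a 5 N threshold on the ground normal force, detected on the
integration grid (the threshold is insensitive between 1 and 50 N
against the ~5 kN stance force); traces are sampled every 0.5 ms, which
resolves the 18 ms impact and the ~40 ms CoC reversal.

Two instruments run alongside the physics: an action–reaction closure sum
over all internal wrenches (ligaments, bushings, articular contact),
which is zero to ~10⁻¹² N in every step, and an energy audit
KE + PE + U_elastic + D_dissipated − W_in, whose residual is reported in
joules and as a fraction of the energy turnover. In conservative
configurations the residual fraction is below 10⁻⁷; in the damped
full-stride scenario it is ~6·10⁻⁴, dominated by the rectangle-rule work
integrals at the prescribed attachments.

## Morphometry

All indices operate on binary voxel volumes (17.5 µm default voxel).

- **BV/TV**: voxel fraction in the VOI.
- **Tb.Th / Tb.Sp / C.Th**: Hildebrand–Rüegsegger local thickness — the
  diameter of the largest inscribed sphere containing each voxel — by
  distance transform plus sphere marking, iterating the inscribed radii
  in descending order with an EDT-based covering test; it agrees exactly
  with naive sphere painting. A periodic (wrap-padded) variant emulates
  structures that continue through the volume border, used for plate
  phantoms; Tb.Sp is the same transform on the complement.
- **Tb.N**: the plate-model relation (BV/TV)/Tb.Th per mm, which is
  self-consistent with literature-table triplets; direct 3-D variants
  are out of scope.
- **Tb.Pf**: 2(S₁−S₂)/(V₁−V₂) across a single-voxel dilation; negative
  for concave, well-connected networks.
- **SMI**: 6·V·S′/S² with S′ = dS/dr, the first variation of surface
  area, measured as Σ edge-length × signed dihedral angle on a
  Taubin-smoothed marching-cubes isosurface of the half-voxel signed
  distance field. Surface areas are mesh areas, not voxel-face areas
  (voxel faces overestimate S by ~1.5× and destroy the plate/rod/sphere
  limits 0/3/4, which this estimator reproduces to ±0.1 axis-aligned and
  ±0.3 under oblique re-voxelisation). Surfaces stay open at the volume
  border so spanning phantoms keep their analytic limit.
- **DA**: mean intercept lengths along 128 Fibonacci-distributed
  directions (seeded random parallel lines, 0.5-voxel sampling), an
  ellipsoid fit of 1/MIL², and DA = 1 − shortest/longest axis — chosen so
  isotropy → 0 and all values lie in [0, 1), matching the sub-1 values
  conventional in the field (some packages report the reciprocal ratio
  ≥ 1). Volumetric mineral density is deliberately not computed
  (frozen-specimen bias).

Measured indices from real scans are *not* reproduction targets: the
study scans are unavailable, so the module is validated exclusively on
phantoms with analytic references, plus the printed-triplet consistency
of the Tb.N relation.

## What the synthetic data does and does not emulate

The IMU generator produces the signal *structure* segmentation relies on
(impact spikes, quiescent stance, swing oscillation, additive Gaussian
noise; optional constant gyro bias, default off) — not realistic gait
variability, soft-tissue artefact or sensor saturation. The geometry
generator produces congruent, smooth facets — not the medial parasagittal
ridge relief, subchondral irregularity or inter-individual shape
variation. Passing tests therefore demonstrate correctness of the
algorithms and internal consistency of the mechanics, not anatomical
fidelity; absolute force levels inherit the uncertainty of the contact
calibration and of the reconstructed micro-motion, which is why the peak
force is quoted with a ±20 % calibration band.

## Numerical and design choices

- Units strictly SI internally; meshes in meters; morphometry I/O in µm.
- PCHIP rather than cubic splines for all drive series: monotone between
  knots, so "first reaches zero at the landmark" holds exactly.
- The mirror model (`medial_sign = −1`) negates every y-coordinate
  (facet layout, attachments, lean, tilt) while keeping bone labels; the
  integrator is sign-symmetric, so mirrored strides match to ~10⁻⁹ N.
- Degenerate inputs raise typed errors (`carposim.errors`): open meshes,
  empty phases/VOIs, non-monotone marker times, out-of-order landmarks,
  missing carpal suspension, dt above dt_max; NaN/Inf in the state aborts
  integration naming the largest force element.
- Problem sizes used throughout the test suite (facet resolution 8–12,
  10 300 integration steps per stride, ≤ 128³ phantom volumes) were
  chosen as the smallest instances that exercise every code path with
  comfortable numerical margins.

## Known limitations

- No muscle–tendon forces: carpal loads are underestimates by design.
- The micro-motion is a reconstruction, not a measurement; its amplitudes
  set the absolute force scale.
- The bushing law is diagonal linear; real intercarpal constraint
  stiffness is coupled and nonlinear.
- Cartilage is a penalty layer, not a continuum: no stress/strain fields
  inside the tissue (a finite-element question, out of scope).
- Ligament paths are straight lines; no wrapping.
- The hoof–ground interaction of a tuff-clay-sand track is reduced to a
  penalty-plus-Coulomb plane with guessed parameters.
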