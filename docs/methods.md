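# Methods

`airwayflow` re-creates, at desk scale, the computational chain that turns an
endoscopic optical-coherence-tomography (OCT) pullback of the upper airway
into a ranked list of obstruction sites: synthetic B-scan generation →
lumen segmentation → curved 3D reconstruction → lattice-Boltzmann airflow →
pressure-derivative localization.  This note records the models, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## The airway phantom

No patient data ships with the package, so the study conditions are defined
by an analytic phantom: a gently curved tube, ~148 mm of arc length, whose
cross-sections are circles (optionally ellipses) of base radius 6.0 mm in
the pharyngeal segments.  Five named region windows partition the arc length
(mm): nasopharynx [15, 40], velopharynx [48, 62], base of tongue [70, 95],
epiglottis [103, 123], hypopharynx [130, 145].  The *asleep* state scales
the cross-sectional areas of the nasopharynx, base-of-tongue, and epiglottic
regions by 0.92, 0.44, and 0.68 — i.e. 8%, 56%, and 32% reductions — with
cosine tapers of 3 mm placed *outside* the window edges.  Placing the tapers
outside the windows makes the in-window area ratio exactly the constriction
factor, so the regional comparison has a closed-form oracle.  The catheter
rides inside the lumen with a slowly varying eccentricity (amplitudes
0.8/0.5 mm), and the electromagnetic tracker samples the catheter path with
isotropic Gaussian noise (default sd 0.1 mm).

Acquisition parameters mirror a long-range swept-source rotational system:
25 frames/s, 2000 A-lines per frame, 12.5 mm/s pullback (0.5 mm frame
spacing), 12.8 mm imaging range over 1024 depth pixels (12.5 µm pitch), and
a 10 µm axial point-spread function.  Ranging inside the air-filled lumen
uses refractive index 1; the tissue index only affects axial resolution in
tissue, not the catheter-to-wall distance.

Image formation per A-line: a specular wall echo (Gaussian of the PSF width)
at the catheter-to-wall range, a scattering tail decaying into tissue with a
1 mm attenuation length, multiplicative Rayleigh speckle (unit mean),
an additive Gaussian noise floor, and a bright ring at the 0.9 mm sheath
radius modeling the specular reflection off the stationary transparent
sheath.  Beams whose wall lies beyond the 12.8 mm range record no echo and
are flagged truth-missing.  What the phantom does *not* emulate: irregular
(non-elliptical) real lumen shapes, non-uniform rotational distortion,
catheter whip, swallowing motion, and tissue-layer contrast.  Passing tests
therefore demonstrate the pipeline's numerics and plumbing, not robustness
to those real-data artifacts.

## Segmentation

The wall is the *near edge* of the echo, so detection is first-threshold-
crossing, not peak finding: the first run of ≥5 consecutive depth samples
above `noise_median + 4·noise_sd` beyond a 1.2 mm exclusion zone (past the
sheath).  The noise floor is estimated from the clear-lumen window
1.2–2.2 mm, with a MAD-based spread so bright outliers cannot inflate the
threshold.  Valid wall radii get a periodic 9-vertex moving average; invalid
sectors are filled by linear interpolation across frames at the same beam
angle (search limit ±10 frames), then by periodic angular interpolation, and
stay flagged as extrapolated so every downstream area report carries an
extrapolated-vertex fraction.  A frame with more than 50% missing sectors is
flagged unusable.  Rotational stack alignment correlates per-angle
wall-distance signatures of consecutive frames (FFT circular
cross-correlation) and applies the cumulative shift.

## Reconstruction

The tracker samples are fitted per coordinate with a smoothing spline
(smoothing factor `n·smooth_mm²`, default `smooth_mm` 0.1), reparameterized
by arc length, and resampled at the 0.5 mm frame spacing.  Frames along the
centerline are rotation-minimizing, computed with the double-reflection
method, so a planar curve accrues no spurious twist (< 1°/100 mm, verified).
Each contour is placed rigidly in its station's normal plane with the
catheter center on the centerline point — rigid placement preserves polygon
area exactly, which is why station areas are measured on the 2D contours
rather than by mesh slicing.  Consecutive rings are roll-registered by the
cyclic vertex shift minimizing summed squared distance, stitched with
triangle strips, capped, and trimmed 5 mm at each end.  For flow runs the
loft can append straight constant-section extensions along the end tangents
(default 20 mm): standard CFD practice that keeps the inlet/outlet boundary
adjustment layers outside the anatomical measurement span.

Areas are shoelace polygon areas; the awake/asleep comparison resamples both
profiles onto a common arc-length grid and reports
`100·(1 − mean_asleep/mean_awake)` per region window.  Areas are measured in
the catheter plane, not perpendicular to the anatomical centerline; for the
gentle curvatures considered the difference is second order in the tilt.

## Lattice-Boltzmann flow

D3Q19 velocity set, halfway bounce-back walls, BGK (SRT) and d'Humières MRT
collisions.  MRT is implemented through the collision matrix
`M⁻¹·diag(s)·M`, with conserved moments at rate 0, shear moments at 1/τ and
the remaining moments at 1.2, so setting every rate to 1/τ reproduces SRT to
round-off.  The velocity inlet (plug profile matching the requested
volumetric flow, ramped over 500 steps) and the fixed-density outlet are
imposed by non-equilibrium extrapolation from the adjacent interior node —
chosen over a Zou–He construction because it is second-order,
orientation-agnostic, and robust on staircase inlets.  Body-force driving
(Guo forcing) is available for periodic validation problems.

Meshes are voxelized by slicing with z-normal planes at every voxel-center
height and testing centers against the closed section polygons; the first
and last *full* cross-section slabs become inlet and outlet (sliver slabs
from slightly tilted end caps are squared off).  A warning is raised when
the narrowest section spans fewer than 10 voxels.

Unit bookkeeping — the classic LBM pitfall — is explicit: given the lattice
spacing dx, the target Reynolds number, and the lattice inlet speed
`u_lat`, the physical inlet speed follows from the flow rate (default
9.45 L/min) and the voxelized inlet area; viscosity is *inflated* so
`Re = U·D/ν` hits the target; and `dt = u_lat·dx/U` fixes
`τ = 3·ν_lat + ½`.  Every field records dx, dt, τ, Re, and the velocity and
pressure scales (`ρ_air·C_u²`).  Reported pressures are model-scale pascals:
because viscosity is inflated, magnitudes are not physiological, but the
*shape* of the pressure profile — all the localization statistic uses — is
Reynolds-similar.

Desk-scale choices: the full airway runs at Re 100 with `u_lat` 0.04 and
dx 0.75 mm (≈10.6 voxels across the constricted base-of-tongue throat,
~37 k fluid nodes, ~15 k steps to the 1e-6 steady criterion, then 500
averaged steps).  At this resolution the expansion jet downstream of the 56%
constriction is numerically unstable for Re ≥ 150, so Re 100 is the default;
the single-constriction validation (40% area reduction, 20 voxels across)
runs stably at Re 200.  Direct simulation at physiological Reynolds numbers
(~10³–10⁴, turbulent, reversing) is explicitly out of scope.  The
oscillatory mode modulates the inflow over a 5 s breathing period mapped
through the time scaling and phase-averages the final cycle; steady mode is
the default and is what the shipped analyses use.

Numerical accuracy, measured by the test suite: plane-Poiseuille channel
error ≤2% at 21 nodes across; circular-pipe profile error ≤5% at 21
nodes/diameter with the pressure drop within 10% of Hagen–Poiseuille; exact
mass conservation (<1e-10 relative over 10⁴ steps); second-order spatial
convergence demonstrated on the plane channel (error ratio ≈4 on dx
halving).  On *curved* walls the staircase bounce-back limits convergence to
roughly first order in the max norm — a known property of the scheme, which
is why the order check uses grid-aligned walls and the pipe provides the
absolute-accuracy checks.

## Obstruction localization

Cross-section-averaged pressures are taken over one-voxel-thick slabs
centered on each station's normal plane, with voxels assigned a continuous
arc-length coordinate (nearest centerline point plus tangential offset), and
referenced to the first station.  First and second axial derivatives use
second-order three-point stencils valid on non-uniform spacing (one-sided at
the ends for dp/dz; d²p/dz² undefined at the ends).  The stencils are exact
on quadratics and are tested against an independent Lagrange-parabola
oracle.

A constriction imprints a characteristic signature on p̄(z): a negative-
curvature shoulder where the flow begins accelerating upstream, and a
positive-curvature trough at the constricted level itself (the local
pressure minimum, partially recovering downstream).  Sites are therefore
ranked by *signed* d²p/dz² descending — the valley curvature — with ties
broken by lower p̄, then the more distal station; ranking is invariant under
pressure offset and uniform rescaling.  A profile whose curvature never
exceeds 1% of its dynamic range per (half-span)² is flagged "no focal
obstruction".

Station placement defaults to anatomical landmarks: one station at each of
the five region centers plus the two trimmed ends (seven in total), which
guarantees the three-point stencil brackets any single region's
constriction.  Equally spaced stations are available
(`obstruction.default_stations`) and arbitrary user stations are accepted;
with stations much coarser than a constriction the statistic can attribute
the signature to a window edge, which is why landmark placement is the
default.  Each station's cross-sectional area is reported alongside its
score as corroboration, never enforced.

## Problem sizes used by the shipped analyses

The regional-comparison analysis renders both states at the full acquisition
geometry (2000×1024, ~296 frames each).  Flow analyses use the truth-contour
loft of the same phantoms (segmentation fidelity is established separately
by the imaging-chain comparison), voxelized at 0.75 mm (full airway,
Re 100) and 0.5 mm (single-constriction, Re 200).

## Known limitations

- Circular/elliptical phantom sections make the area oracle exact but do not
  probe segmentation on irregular lumens.
- The voxelizer slices along +z and assumes a tube-like mesh transverse to
  it; strongly recurved airways would need an oriented slicing axis.
- Localization resolution is one station spacing; sub-station localization
  would need denser stations and a longer flow average.
- The steady-flow assumption breaks down at higher desk-scale Reynolds
  numbers (jet unsteadiness); the oscillatory mode exists but phase-resolved
  statistics are not validated beyond smoke level.
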