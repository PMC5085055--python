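# Methods

`corneafit` reconstructs the inherent hyperelastic constants of a cornea or
corneal phantom from non-contact air-puff deformation imaging, and
cross-validates the result against uniaxial extensiometry.  This note
documents the models, the numerical choices, and what the synthetic test bed
does and does not establish.

## Constitutive model

The cornea is a two-parameter Mooney-Rivlin solid,

    W = C10 (Ī₁ − 3) + C01 (Ī₂ − 3) + κ/2 (J − 1)²,

with Ī₁, Ī₂ the isochoric invariants of the Cauchy-Green tensor and J the
volume ratio.  The material is treated as incompressible; a pure-displacement
finite-element formulation needs a volumetric penalty, so κ defaults to
1000 µ (µ = 2(C10+C01)), which puts the effective Poisson ratio at ≈0.4995
and keeps volume changes below 0.1% at the loads of interest.  Whether the
deviatoric term uses full or isochoric invariants is immaterial at this
penalty (the two differ at order (J−1)); the isochoric split is used because
it cleanly separates the penalty from shape change.  Viscoelasticity and
anisotropy are deliberately out of scope: the hydrogel phantoms the method
is validated on are isotropic and show temporal deformation profiles that
track the pulse pressure, i.e. negligible time dependence.

Small-strain identities used throughout: shear modulus µ = 2(C10+C01),
incompressible Young's modulus E = 3µ = 6(C10+C01).  The exact
incompressible uniaxial response P(λ) = 2(λ − λ⁻²)(C10 + C01/λ) is the
independent oracle for the finite-element machinery.

## Forward model of the air-puff test

Geometry: anterior and posterior corneal surfaces are concentric spheres
(uniform thickness); the shell is bonded at its periphery to a stiff elastic
holder ring (E = 1500 MPa, ν = 0.3) representing the artificial-chamber
clamp.  The holder's published dimensions are unknown; the default ring has
a 5.5 mm inner aperture, 2 × 2 mm cross-section, outer and bottom faces
fixed, and the corneal overhang shares nodes with its upper face.  All of
this is configuration, not hard-coded.

Discretisation: structured 4-node axisymmetric quadrilaterals,
total-Lagrangian kinematics, 4 × 100 elements through
thickness × meridian by default (doubling both resolutions changes the
deformation amplitude by ~0.7%).  Near-incompressibility uses selective
reduced integration: deviatoric stress at the 2×2 Gauss rule, volumetric
penalty at the element centre.  A clamped-plate bending benchmark at
radius/thickness = 20 agrees with Kirchhoff theory to ~3%, confirming the
formulation does not lock.

Loads: the intraocular pressure (15 mmHg via a water column; 1 mmHg =
133.322 Pa) acts as a uniform follower pressure on the wetted posterior
surface — statically equivalent to pressure-prescribed interior fluid
elements, so no fluid unknowns are carried.  The air pulse is a separable
field p(r,t) = p₀ exp(−r²/2σ²) a(t) with a(t) = sin²(πt/T) over T = 30 ms,
sampled by 140 frames (≈4.7 frames/ms).  The instrument's true footprint is
proprietary; a measured radial table can be substituted via configuration.
The default p₀ = 4.5 kPa, σ = 1.5 mm was calibrated once so that the
phantom presets span deformation amplitudes 0.6–1.6 mm, the range such
phantoms show in the real instrument; it was frozen before any recovery
experiment was scored.  Because the pulse magnitude is an instrument
constant, reconstructions from *real* instrument exports inherit its
calibration uncertainty; the synthetic validation path is unaffected
(generator and inverse loop share the same pulse).

Both pressures are follower loads (normal to the deformed surface, with the
load-stiffness term in the tangent).  The pulse magnitude at a surface point
is evaluated at its reference lateral coordinate, i.e. the footprint is
material-attached; at the observed displacements (≤1.6 mm at r≈0 where the
footprint gradient vanishes) the difference from a spatially-fixed footprint
is negligible.

Time stepping: the model is quasi-static and elastic, so each frame is an
equilibrium problem at the instantaneous pulse amplitude, and frames with
equal amplitude have identical solutions.  A full record therefore solves
the ~70 unique amplitudes in ascending order with warm starts; the apex
trace of a temporally symmetric pulse is exactly symmetric by construction.
The pre-puff reference state is the IOP-inflated configuration (the nominal
geometry is taken stress-free), and all reported displacements are relative
to it, positive toward the eye.

Solver: full Newton with exact consistent tangents (constitutive derivatives
by complex-step differentiation of the analytic S(C), machine-precision
accurate), direct sparse factorisation, automatic load-increment halving (≤5
consecutive halvings), and a backtracking guard only against inadmissible
trial states (J ≤ 0) — thin-shell force residuals are strongly non-monotone
over early iterations, so no sufficient-decrease line search is imposed.
Convergence: ‖R‖ ≤ 10⁻⁶ · max(‖f_ext‖, ‖reactions‖), with a
displacement-stagnation fallback (‖Δu‖ ≤ 10⁻¹²‖u‖) for states at the
round-off floor of the assembled residual.

## Deformation metrics and merit

From a record: HC is the frame of maximal apex displacement; DA the apex
displacement there; PDA the mean displacement linearly interpolated at
exactly ±2.0 mm; CPR = DA/PDA; THC the HC frame time.  The inverse fit
minimises Φ = |ΔDA| + w|ΔCPR| with w = 1/3 by default.  The weight mixes a
mm-valued and a dimensionless residual; any positive w yields the same
zero-merit optimum when an exact fit exists, so w only matters under model
mismatch (it is configurable).

Comparison statistics: profile RMS is computed on a shared uniform grid
(spatial profiles windowed to the central ±4 mm); stress-strain
"point-to-point correspondence" is 100·(1 − mean relative deviation) over a
uniform strain grid, with the reference stress floored at 1% of its
range-maximum so the relative error is defined at the origin.

## Inverse loop

Efficient-global-optimisation structure over (C10, C01): a 20-point Latin
hypercube in log₁₀ space (plausible moduli span a decade), FE evaluation of
Φ at every sample, a Matérn-5/2 Gaussian-process (Kriging) surrogate of Φ, a
seeded real-coded genetic algorithm (population 40, 50 generations,
tournament selection, blend crossover, Gaussian mutation) minimising the
surrogate mean, and FE verification of each GA optimum, which then enriches
the sample set.  The loop stops at an FE-verified Φ ≤ 0.005 or at 80 FE
evaluations; diverged forward solves receive a large finite merit and are
logged.  The reported merit is recomputed by one final cold-started forward
run, so the result is auditable against its own evaluation log, and every
stochastic element derives from one seed (bit-reproducible fits).

**Identifiability.** DA and CPR respond almost exclusively to the overall
stiffness 6(C10+C01): at fixed stiffness, sweeping the split c01/c10 from 0
to 5 moves DA by only ~0.017 mm and CPR by ~0.001.  The merit valley along
constant stiffness is therefore flat at the level of the stopping tolerance
and far below the default measurement noise, and the individual constants
are not separately identifiable from these two metrics.  The equivalent
Young's modulus is the quantity this method determines (to a few percent);
C10 and C01 individually can land anywhere in the valley.

## Tensile cross-validation

Strip tests (16 × 3 × 0.55 mm specimens, 12 mm free length; loading rate
recorded but inert in an elastic model) are simulated with the closed-form
incompressible solution; an FE bar mode (equal-section axisymmetric
cylinder under prescribed end displacement — the homogeneous uniaxial state
is independent of section shape) cross-checks the machinery to <0.1%.  The
equivalent Young's modulus is the 0→0.1 secant of the nominal
stress-strain curve ("average slope over 0–0.1 strain"); an OLS-slope
variant is provided since the definition is ambiguous at the ~1% level for
these curvatures.  A maximum-force truncation rule emulates the protocol
used for corneal strips.

## Synthetic test bed

The generator forward-simulates a study at known (C10, C01) and adds
i.i.d. Gaussian noise: 0.010 mm on every sampled surface height and trace
sample (≈ sub-pixel segmentation error of a 640×480 Scheimpflug frame
spanning ~10 mm; no noise figure is published, so this is the package's
choice), and 2% multiplicative noise on tensile stress.  Phantom presets G,
S, Q reproduce the manufacturer moduli 0.16/0.30/0.38 MPa with a fixed
split C01 = C10/2, at thicknesses 350/450/550 µm.

What passing the synthetic battery shows: the forward model, metrics,
surrogate loop and tensile validation are mutually consistent, and the
pipeline recovers the identifiable stiffness to a few percent under
realistic sampling and noise.  What it does not show: correctness of the
absolute pulse calibration for any real instrument, nor adequacy of the
isotropic elastic model for real corneas (which are viscoelastic and
anisotropic); both limits are inherent to the method, not the
implementation.

Note on peak-picking bias: DA is the maximum of a noisy trace, so it is
biased upward by roughly the noise level times the expected maximum of the
~20 near-peak samples (~0.02 mm here, i.e. ~2% in the recovered modulus).
This is part of the emulated measurement process, not an artefact.

## Problem sizes used in the shipped studies

Unit tests exercise the physics on a 3 × 48 mesh with 27 frames; the
acceptance battery and the acceptance script run the production 4 × 100
mesh with the full 140-frame sampling, five noisy recovery studies, one
noiseless fit and the three-thickness robustness study.  These sizes are the
package's own defaults and were chosen for a comfortable desk-scale run.
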