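# Methods

This note documents the models, algorithms, and numerical choices behind
`mocapuq`, and what the synthetic fixtures do and do not establish about
real motion-capture data.

## Link-segment model

The skeletal model is a tree of rigid segments rooted at a free-floating
base. Joints are kinematically constrained: free (3 translations along
the parent axes followed by 3 intrinsic rotations), ball (3 rotations),
universal (2), and pin (1). Rotation axes are unit vectors expressed in
the parent frame and applied as successive intrinsic rotations, so a
ball joint with axes z, x, y reproduces the familiar
flexion/adduction/rotation ordering of gait models. Frames are
right-handed, x forward, y up, z lateral. Coordinate bounds default to
±π for rotations and ±10 m for base translations and are overridable per
joint.

Generalized coordinates are the concatenated joint coordinates in
segment order. Forward kinematics composes the segment transforms; the
geometric Jacobian of marker positions is analytic
(∂m/∂q_k = a_k × (m − o_k) for a rotation about ground-frame axis a_k
through joint center o_k, and a_k itself for a translation), which is
what makes the per-frame IK solves and the scaling rejection sampler
affordable.

### Scaling semantics

`scale_model` multiplies, componentwise per segment: the child
joint-center offset by the *parent's* factors (the knee location is a
thigh dimension), and the center of mass and marker local positions by
the segment's *own* factors (markers ride with the anatomical frame, so
their ground positions change with segment dimensions). Mass properties
scale with geometric similarity — mass by the factor product (volume),
each inertia component I_ab by volume·f_a·f_b (mass × length²) — so
inverse-dynamics outputs respond to scaling; `preserve_mass_properties`
disables this. Scale factors may be isotropic scalars (default) or
per-axis triplets.

## Inverse kinematics

Each frame minimizes Σ w_i‖m_i(q) − o_i‖² subject to coordinate bounds
with a trust-region-reflective least-squares solver (analytic Jacobian,
gtol 1e-10, xtol 1e-12, 200-iteration cap; exceeding the cap raises with
the final residual). A frame needs at least three non-collinear usable
markers; markers that are missing (masked/NaN) or zero-weighted are
excluded from that frame's objective, and frames left with fewer than
three usable markers are flagged and filled by linear interpolation in
the coordinate domain. Trajectory solves warm-start each frame from the
previous solution (frame 0 from the model's neutral pose or a caller
guess), making the solve deterministic and batch-invariant.

A damped Gauss–Newton variant of the same objective (`gauss_newton_pose`)
serves the high-volume single-frame pose checks of the scaling sampler;
it is cross-checked against the trust-region solver in the tests and
agrees to ~1e-15 on well-conditioned poses.

## Signal processing

Coordinates are unwrapped (rotational coordinates only), filtered with a
zero-phase 4th-order Butterworth low-pass (effective order 8 after the
forward–backward pass; DC gain exactly 1) at a 6 Hz default cutoff — the
standard choice for gait kinematics — then differentiated with
second-order central differences (one-sided at the ends; accelerations
by applying the same operator twice). Filtering then differentiating a
band-limited signal reproduces the analytic derivative within 2% away
from the boundary frames.

## Inverse dynamics

A recursive Newton–Euler pass over the tree: the outward sweep
propagates angular velocity/acceleration and linear acceleration from
the base using the per-coordinate ground-frame axes; the inward sweep
accumulates each segment's inertial wrench (I α + ω×Iω about the center
of mass, m(a_com − g)), subtracts applied external loads (force at a
ground-frame point plus free moment), adds child joint wrenches, and
projects the transmitted wrench onto the joint's coordinate axes. The
free base cannot be actuated; its six generalized-force components are
the residual wrench and are returned with the joint moments
(`JointMoments.residual()`), never absorbed or hidden. Correctness is
established against closed-form pendulum solutions, an independently
derived symbolic (Lagrangian) double-pendulum oracle, load linearity,
and a power/energy balance on conservative trajectories.

External loads are linearly resampled onto the kinematic time base;
where the force magnitude is below 10 N the center of pressure is zeroed,
since CoP is numerically meaningless at near-zero load and would inject
spurious moments. Joint powers are the elementwise product of
generalized forces and coordinate velocities.

## Uncertainty propagation

**Registration sampler.** Each marker's local position is offset
independently by a draw uniform in the closed ball of radius *e*:
uniform draws in the cube [−e, e]³ rejected outside the ball (acceptance
probability π/6; a defensive draw cap guards the loop). Uniformity is
verified by the exact identities E‖X‖ = 3e/4 and F(r) = (r/e)³
(Kolmogorov–Smirnov at α = 0.01 on 10⁵ draws). An optional per-marker
radius map supports markers with differing registration uncertainty.

**Scaling sampler.** Candidate per-segment factors are drawn uniformly
on [0.90, 1.10] (configurable); the scaled model is re-posed by IK
against the original model's calibration-pose marker positions and
accepted iff every marker lies within *e*. The first accepted candidate
in draw order is returned, so seeded runs are reproducible. Acceptance
from the full interval is rare at small *e* (~10⁻⁴ at e = 5 mm on the
fixture), so candidates are pre-screened with a rigorous reject-only
bound: same-segment marker distances are pose-invariant, hence a scaled
pair distance differing from the original by more than 2e certifies that
no pose can fit — such candidates are rejected without an IK solve. The
pre-screen cannot change which candidate is accepted, only skip futile
solves. A draw cap (default 2×10⁵) converts pathological configurations
into an explicit error advising a larger *e* or a narrower interval.

**Ensembles.** N fresh models are generated at every uncertainty level
(defaults: e ∈ {0.5, 1, 1.5, 2} cm, N = 100). With `augment_previous`
(default on) the analysis set at each level is the union of all lower
levels' sets, which is the nested "augmentation" protocol; with it off,
each level is analyzed on its own N fresh models. The two readings exist
because "N models at each level" and cumulative augmentation are both
defensible study designs; nesting guarantees per-metric ranges weakly
widen with *e*, and that property is asserted on every run. Randomness
uses one substream per (level, draw index)
(`default_rng([seed, level, draw])`), so ensembles are reproducible and
independent of generation order.

**Pipeline and metrics.** Every ensemble member is run through the
identical pipeline — IK, 6 Hz filter, differentiation, inverse dynamics
with the same measured loads, powers, peak extraction — against the same
experimental inputs; per-model failures are recorded with provenance and
the run continues. Marker-error metrics are defined so they measure
modeling uncertainty, not tracking quality: per-model distances are
computed against the *original*
model's markers posed by the original IK solution (not the experimental
markers); the per-frame RMSE across tracked markers is averaged over
frames and maximized over models, and the single worst marker error over
all markers, frames, and models is reported. The qualitative acceptance
requirement is that the first metric stays below *e* at every level.

**Peak metrics.** Nine scalar outcomes per model: peak hip extension
angle, minimum stance knee flexion angle, peak ankle plantarflexion
angle (degrees); peak hip flexion moment, peak stance knee flexion
moment, peak ankle plantarflexion moment (N·m); peak hip push-off power,
minimum stance knee power, peak ankle push-off power (W). Stance is
detected as vertical GRF > 20 N with 5 N exit hysteresis; the push-off
window is the final 40% of each stance period — standard gait-lab
conventions, fixed here and documented because the metrics depend on
them. Angle/moment sign conventions (flexion and
dorsiflexion positive) are carried by `PeakConfig` so the metrics are
well-defined for any coordinate naming.

**Classification.** Minimum stance knee flexion maps onto crouch-gait
severity: below 15° typically developing, 15–30° mild, 30–50° moderate,
above 50° severe, with boundary values assigned to the higher-severity
class. `classification_range` returns every category a model ensemble's
closed angle range intersects and flags ambiguity when there is more
than one — the mechanism by which calibration uncertainty becomes
classification uncertainty.

## Synthetic gait fixture

The fixture model is a two-legged lower body (free pelvis, ball hips,
pin knees and ankles; 16 coordinates) with 14 markers (4 pelvis, 5 per
leg) and Winter-style segment mass fractions summing to a subject mass
of 83.5 kg. The generator prescribes smooth periodic joint curves (≤3
harmonics per coordinate with gait-plausible amplitudes: hip flexion
−10..30°, knee flexion ~5..45°, ankle −17..7°, 1.2 m/s progression; one
1.0 s cycle at 100 Hz by default), builds marker trajectories by forward
kinematics with optional isotropic Gaussian noise (default 0), and
constructs external loads from whole-body dynamics: the required net
wrench Σmᵢ(a_i − g) with its moment is split between the feet by a
smooth double-support transition weight (12% of the cycle per
transition, right stance ending at 62%), applied as a force at a
center-of-pressure projected under each foot plus a free moment
absorbing the remainder. Because the loads satisfy the same equations of
motion the inverse-dynamics pass solves, the generate → IK → ID triangle
closes on the stored ground truth to <1e-6 (and the base residual
vanishes) at zero noise, and degrades monotonically with marker noise.

What the fixture does *not* emulate: soft-tissue artifact, marker
occlusion patterns, instrument noise spectra, force-plate crosstalk,
double-support force sharing of a real subject, or subject-specific
geometry. Passing tests therefore demonstrate the correctness of the
propagation machinery and the qualitative behavior of the uncertainty
metrics, not the numeric uncertainty magnitudes of any particular
laboratory's data.

## Problem sizes and tolerances

The shipped acceptance checks run a scaled-down study — N = 20 models
per level at e ∈ {0.5, 1, 2} cm for both strategies in the test suite,
N = 10 in `scripts/acceptance.py` — which is sufficient for the
qualitative assertions (max RMSE below *e*; nested ranges weakly
widening; classification boundary behavior) while keeping a full run in
the minutes range on one CPU. Key tolerances: forward kinematics agrees
with an independent homogeneous-transform oracle to 1e-12 m; IK recovers
noise-free generating angles to <1e-6 rad; inverse dynamics matches
closed-form and symbolic oracles to 1e-8/1e-9 N·m; the identity ensemble
reproduces the baseline pipeline bit-for-bit.

## Known limitations

* Joints are limited to free/ball/universal/pin; no custom joints,
  couplers, or closed loops.
* The IK solver reports local minimizers; with the analytic Jacobian and
  warm starts this is robust for gait-like motions but a poor frame-0
  guess on an arbitrary pose can land in a different basin.
* Inverse dynamics assumes rigid segments and noise-free segment mass
  properties; only registration and scaling uncertainty are propagated
  (inertial and joint-axis uncertainty are out of scope).
* The base residual is reported but no residual-reduction is attempted.
* C3D import is not implemented; TRC/MOT/STO text formats only.
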