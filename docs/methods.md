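# Methods

This note documents the models and numerical procedures implemented in
`bimanum`, the assumptions behind them, and the choices made where the
design was genuinely open.

## 1. Bilateral model construction by reflection

A unilateral model (OpenSim 3.3 dialect) is reflected across the plane
through the ground origin whose normal is the medial/lateral axis
(configurable; default z). Writing M for the reflection matrix
(diag with one −1):

* **Points and vectors** (COM positions, joint frame origins, muscle path
  points, translation axes): p → M p.
* **Inertia**: I → M I Mᵀ, which negates the two products involving the
  mirror axis and preserves eigenvalues. The original procedure we follow
  only reflects COM positions; we also reflect the products because a
  mirrored body with unmirrored products would be dynamically asymmetric.
* **Orientations** (body-fixed XYZ Euler frames): R → M R Mᵀ, which is a
  proper rotation (det +1). With the z-normal convention, x- and y-Euler
  angles negate and the z angle is preserved.
* **Rotation axes of custom joints**: conjugation gives
  M R(a, q) Mᵀ = R(M a, −q). Rather than negating the coordinate, we use
  the identity R(M a, −q) = R(−M a, q) and store the flipped axis −M a with
  the coordinate value, range and default unchanged. This *coordinate-sign
  policy* is the load-bearing convention of the package: identical joint
  angle vectors applied to the two sides produce exactly mirror-symmetric
  postures, verified by a forward-kinematics oracle (right-side stations
  land on the mirror image of their left twins, and left/right muscle
  lengths agree, to well below 1e-9 m on the test fixture — in fact
  bit-exactly, because reflection only negates z components, which enter
  path lengths squared).
* **Meshes**: vertices reflected, triangle winding reversed so outward
  normals remain outward; normals are recomputed rather than mirrored.
  Mirrored mesh files are named `<stem>_mirrored.<ext>`; the marker toggles
  so that double mirroring restores the original name.
* **Merging**: side-suffixed components (default `_r` ↔ `_l`) gain mirrored
  twins; shared trunk/ground components appear once; name collisions abort.

The full mirror is an involution (applying it twice reproduces the model to
1e-12 relative), which the suite checks structurally and numerically.

Euler extraction at gimbal lock (|pitch| = π/2 within 1e-9) sets the third
angle to zero and folds the degenerate parameter into the first angle, so
round trips are deterministic.

## 2. Tear severities and the shared load

Rotator-cuff-tear severity scales peak isometric force of the affected
side's cuff actuators, on the assumption that force capacity is linear in
the fraction of intact tendon:

| severity | supraspinatus | infraspinatus | subscapularis |
|----------|---------------|---------------|---------------|
| none     | 100%          | 100%          | 100%          |
| partial  | 50%           | 100%          | 100%          |
| full     | 0%            | 75%           | 100%          |
| massive  | 0%            | 25%           | 50%           |

Teres minor is never scaled. The pristine F_max values are snapshotted on
the first application, and every severity scales that baseline, so applying
severities in sequence never compounds. The affected side defaults to the
model's right. Muscle atrophy, fatty infiltration and pain-driven kinematic
change are out of scope.

The shared load is a box body welded to the left hand with a weld
constraint closing the loop to the right hand, COM midway between the hand
COMs in the default (arms extended, thumbs up) posture. Weights follow the
source protocol (13.3 N and 44.5 N); mass is derived as W/g with
g = 9.80665 m/s², because the printed weight/mass pairs are mutually
inconsistent (44.5 N vs 4.5 kg) and we treat the weight as authoritative.
The load body's inertia is a uniform 0.2 × 0.2 × 0.4 m box — irrelevant for
static tasks and second order for the slow reach.

## 3. Task battery

All tasks are generated bilaterally with identical left/right coordinate
values (valid under the coordinate-sign policy), 7 s duration, wrist
coordinates locked at 0°, and sampled at a configurable rate:

* **Low static hold**: shoulder elevation 80°, elevation-plane angle 80°,
  elbow extended (0°) — a box held with extended arms at waist height.
* **High static hold**: elevation 130°, plane 80° — a box held above eye
  height.
* **Dynamic forward reach**: from arms at the side with 90° elbow flexion,
  the humerus elevates along a minimum-jerk out-and-back profile to a 75°
  peak at mid-task; the elbow extends linearly with the profile from 90°
  toward 20°. The source protocol used one participant's recorded
  kinematics (not published), so the profile shape (minimum jerk, peak at
  mid-duration) and the elbow coupling are this package's choices; recorded
  kinematics can be substituted by passing any `.mot` table. The protocol's
  "≈75° elevation angle" peak is interpreted as the humeral elevation
  magnitude; the elevation-plane coordinate is held at 80°, consistent with
  the static holds.
* **Verification tasks** (unloaded, for symmetry checks): a static hold at
  0° elevation, 0° elbow, −25° shoulder rotation; and a dynamic 0→90→0°
  elevation excursion at −45° rotation.

Kinematics are smoothed with a zero-phase low-pass Butterworth filter,
cutoff 6 Hz. The effective order (default 4) is achieved as an order/2
design applied forward and backward — the biomechanics convention for an
"Nth-order zero-lag" filter; the cutoff is passed to the design
uncompensated, so the dual-pass amplitude at the cutoff is exactly 0.5.

## 4. Reduced muscle-redundancy solver

The original simulations used a closed-loop tracking controller with
activation and contraction dynamics. For 7 s quasi-static tasks, per-step
static optimization is the accepted surrogate, and that is what this
package implements; reproducing the controller is out of scope.

At each time step with posture q:

* **Moment arms** r_ij = −∂L_i/∂q_j by central finite differences of
  musculotendon path length, step 1e-5 rad. One "sweep" (2·n_dof + 1 forward
  kinematics evaluations) yields all moment arms, COM and station Jacobians
  and the gravity demand.
* **Gravity demand** τ_j = ∂V/∂q_j via virtual work over all segments,
  validated against an independent finite difference of the total potential
  energy.
* **Load sharing.** Because kinematics are prescribed (the weld loop is not
  dynamically closed), the load is reduced to its mass at the midpoint of
  the two hand stations, supported by a force and a grip moment at each
  hand. The load's full static equilibrium is eliminated exactly, leaving a
  6-vector of free variables: the deviation φ of the right-hand force from
  the equal half-share and the antisymmetric grip-moment component μ.
  Shifting vertical share toward one hand then *requires* stabilizing grip
  moments on both wrists (from the load's moment balance), which is the
  mechanical pathway by which the unaffected limb compensates. The
  parameterization is exactly mirror-symmetric, so symmetric tasks at
  severity `none` yield bitwise-symmetric demand and (to solver precision)
  identical left/right recruitment. Free weld *moments acting across the
  unclosed loop* are deliberately not exposed to the optimizer: with
  prescribed kinematics they would act as fictitious external actuators. A
  zero-weight load is treated as inert (no interaction variables), so the
  zero-load limit reproduces the unloaded statics exactly.
* **The program.** minimize Σa² + w‖τ_s‖² + λ‖ω‖² subject to torque balance
  and 0 ≤ a ≤ 1, with slack weight w = 1e6 (N·m)⁻² and sharing
  regularization λ = 1e-8 (the minimal term making the program strictly
  convex in ω). Muscles are rigid-tendon and activation-linear
  (F = a·F_max); force–length/velocity scaling is omitted because the
  pathology model modulates only peak isometric force. Eliminating the
  slack turns the program into a bounded least-squares problem solved by an
  active-set method (BVLS); the slack is then *defined* as the balance
  residual, so the torque-balance identity holds to machine precision. A
  step counts as feasible when ‖τ_s‖∞ < 1e-4 N·m (interior solutions leave
  a penalty-induced residual of order 1e-8 N·m; true saturation produces
  slack of order 1 N·m, so the threshold sits in a wide gap). Consecutive
  identical postures reuse the previous solution, so static holds cost one
  optimization regardless of sampling rate.
* **Cost exponent**: 2 (sum of squared activations). The minimizer of the
  strictly convex program is unique, so no tie-breaking is needed.

### Load deviation surrogate

The original workflow tracked the box with a point-kinematics analysis of
the controller's output; deviation emerged when the controller could not
follow the commanded motion. Here the analogue is explicit: unmet demand
relaxes the posture along the slack with a uniform joint compliance c
(default 0.01 rad/(N·m)), Δq = −c·τ_s, and the load COM moves with the
posture through its point Jacobian, δ = J Δq. Feasible steps map to exactly
zero deviation. The mapping preserves the physically required sign
structure — an elevation deficit moves the load inferiorly; an
injured-side-dominant deficit moves it toward the unaffected side — but its
magnitude is proportional to the arbitrary compliance, so deviations are
comparable across permutations of this package, not with externally
reported millimetre values.

Directions follow the ground frame: y vertical (negative = inferior), z
mediolateral with the affected side at +z ("toward the unaffected side" =
negative z, reported as a positive magnitude).

## 5. The synthetic model

All tests and the acceptance script run on a generated right-side-only
model: thorax welded to ground, humerus (0.30 m, 2.0 kg) and a combined
forearm+hand segment (0.30 m, 1.5 kg); a three-rotation shoulder
(elevation-plane about +y, elevation about −x after the plane rotation,
axial rotation) plus elbow flexion, with pronation and wrist flexion
present but locked; and the 14 shoulder-crossing muscle paths whose forces
the analysis reports (three deltoid and three pectoralis-major and three
latissimus compartments, the four cuff muscles, teres major), each a
straight two-point path placed to give usable moment arms. Peak isometric
forces are order-of-magnitude literature values (e.g. supraspinatus 487 N,
infraspinatus 1210 N, subscapularis 1378 N) chosen once; they are *not* the
values of any published cadaver-derived model, and the generator does not
model path wrapping, via points, scapular kinematics or glenohumeral
translation. Consequently the suite's solver-output checks are
property-based (symmetry, monotonicity, feasibility, sign structure), never
numeric comparisons with published simulation results: passing tests show
the machinery is correct, not that the synthetic model reproduces any
specific shoulder.

## 6. Problem sizes and determinism

The acceptance script samples static holds at 20 Hz (they deduplicate to a
single optimization per permutation) and the dynamic reach at 50 Hz
(351 steps), over all 4 severities × 2 loads × 3 tasks; the whole run,
including the property metrics, completes in well under a minute on one
CPU. Everything is deterministic given the seed: the generator is
seed-stable, the QP is solved by an exact active-set method, and repeated
simulations are bit-identical.

## 7. Known limitations

* Quasi-static treatment of the dynamic reach (inertial torques neglected)
  — the main fidelity gap versus the original tracking controller.
* No activation/contraction dynamics, force–length/velocity effects, path
  wrapping, joint contact forces, humeral-head translation or scapular
  rhythm; no EMG validation.
* The deviation magnitude depends on an arbitrary compliance constant
  (signs and zero/nonzero structure do not).
* The grip is a rigid weld: no grip-force limits or friction cone, so the
  optimizer may brace one hand against the other (a real but unbounded
  mechanism here).
* Severity scaling assumes force capacity linear in torn-tendon fraction
  and leaves muscle paths unchanged.
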