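# Methods

## Model

The plant is a planar two-segment arm (upper arm, forearm) with revolute
shoulder and elbow joints, moving in a horizontal plane at shoulder height —
gravity therefore never enters the equations of motion.  Segment masses,
centre-of-mass offsets, lengths and moments of inertia are the published
values for this model (upper arm 1.93 kg / 141 kg·cm² / 290 mm / CoM 145 mm;
forearm 1.52 kg / 188 kg·cm² / 300 mm / CoM 150 mm).  Joint dynamics are the
standard two-link form `M(q) q̈ + C(q, q̇) q̇ + D q̇ = R(q) F`, with `D`
optional viscous damping (default 0) and `R(q)` the 2×6 tendon-excursion
moment-arm matrix.

Six lumped muscle groups actuate the arm: mono-articular shoulder
flexor/extensor, mono-articular elbow flexor/extensor, and a bi-articular
flexor/extensor pair.  Maximum isometric forces, tendon slack lengths and
pennation angles are the published constants (e.g., shoulder flexor
2525 N / 29.2 mm / 21.6°).  The state is 10-dimensional: two angles, two
angular velocities and the six muscle activations; the controls are the six
neural excitations in [0, 1].

### Muscle model

The contraction model is a **rigid-tendon Hill muscle**: with no
fibre-length states in the plant, the fibre length is algebraic — path
length minus tendon slack, divided by the (constant) pennation cosine.
Tendon force is

    F = F0max · cos(α_p) · ( a · f_L(l̃) · f_V(ṽ) + f_PE(l̃) ),  clamped ≥ 0.

- `f_L`: Gaussian active force–length, `exp(−((l̃−1)/0.45)²)`.
- `f_V`: a single analytic Hill-like force–velocity curve built from a
  softplus — exactly 1 at zero velocity with slope `1 + 1/0.25`, zero at a
  maximal shortening velocity of 10 optimal fibre lengths/s, saturating at
  an eccentric plateau of 1.4.  A piecewise concentric/eccentric switch was
  deliberately avoided: direct collocation loses its design convergence
  order when the vector field has kinks inside the operating range, and for
  this arm the fibres operate at |ṽ| ≲ 0.1 where a kink at ṽ = 0 would sit
  exactly on the operating point.
- `f_PE`: exponential passive stretch response in a softplus-smoothed
  stretch variable, shifted to be exactly zero at optimal length and
  reaching 1 at 1.6 optimal lengths.  Below optimal length the residual is
  |f_PE| < 10⁻³.

Excitation-to-activation coupling is first order with time constants
τ_act = 10 ms and τ_deact = 40 ms; the switch between the two constants at
`u = a` is blended by a sigmoid of width 0.02 so the dynamics stay
differentiable (at the blend centre the rate is the mean of the two, and the
fixed point a = u is unchanged).

### Attachment geometry and calibration

The published model's attachment coordinates and optimal fibre lengths were
tuned against a three-dimensional shoulder model that is not available, so
this package ships its own straight-line origin/insertion geometry
(`data/default_model.yaml`, fully overridable).  Two rules governed the
choice, applied before any closed-loop experiments were run:

1. moment arms of constant sign and roughly 2–4 cm magnitude over the
   motion range (flexors positive, extensors negative; mono-articular
   muscles have identically zero moment arm about the joint they do not
   span);
2. musculotendon paths long enough that the **operating fibre length stays
   within about [0.7, 1.35] of optimal** across the motion range.  Short
   paths make l̃ hypersensitive to joint angle and turn a muscle into a
   stiff passive spring around the calibration posture — an early draft
   with a short elbow-extensor path produced hundreds of newtons of passive
   force at moderate elbow flexion, which is not physiological and blocks
   flexed-posture targets.

Optimal fibre lengths are calibrated so every fibre is exactly at optimal
length at the natural initial posture (shoulder 44°, elbow 58°); this also
makes that posture an exact passive equilibrium.

## Optimal control transcription

Each finite-horizon problem minimizes

    J = ∫ p‖ζ(t) − ζ_des(t)‖² + q Σᵢ uᵢ²(t) dt

(hand position ζ from the forward kinematics; defaults p = 20, q = 1 for
goal-directed reaching) subject to the dynamics and 0 ≤ u ≤ 1, with an
optional terminal equality on selected state components and an optional
terminal-cost hook (disabled by default).  The horizon is transcribed by
flipped Legendre–Gauss–Radau collocation on K equal intervals of degree d
(default d = 3): states are degree-d Lagrange polynomials through the
interval start plus the d Radau nodes, controls degree-(d−1) polynomials
through the same nodes, dynamics enforced as defect constraints at the
collocation points, the cost by Radau quadrature.  Activations carry [0, 1]
bounds as states; the initial state is a constant, and interval continuity
is implicit because the last Radau node is the interval's right endpoint.

Derivatives are exact: the dynamics are evaluated complex-step-transparently,
so constraint Jacobians are assembled from machine-precision per-node
Jacobian blocks, and the objective gradient is analytic.

### NLP solver

No general sparse NLP solver is assumed; the package ships a small
primal-dual interior-point SQP (`reachmpc.nlp`) tailored to collocation
structure: bounds are handled IPOPT-style (explicit bound multipliers with
complementarity s·z = μ), equalities by damped Newton steps on the sparse
barrier KKT system, globalized by an ℓ1 exact-penalty line search with a
second-order correction step and adaptive Levenberg damping.  The Lagrangian
Hessian is approximated by partitioned Powell-damped BFGS blocks, one per
collocation node, seeded with the objective's Gauss-Newton block — the
constraint nonlinearity of a collocation NLP is separable by node, so these
small blocks capture the curvature while the KKT systems stay sparse.
Barrier tolerance 10⁻⁷, feasibility tolerance 10⁻⁶.  scipy's SLSQP is kept
as an alternative engine (`solve_ocp(..., method="slsqp")`) and as a
cross-check.

Two practical properties of this problem class shaped the solver:

- **Flat cost valleys.**  The muscles are strong relative to the task, so
  wide co-contraction subspaces change the objective by very little.  The
  solver therefore also terminates when the iterate is feasible, the barrier
  is at its final level and the objective has stopped moving ("objective
  stall at feasibility"); solutions are near-optimal rather than
  KKT-converged, which is sufficient for closed-loop control and is reported
  honestly in the diagnostics.
- **Control ringing.**  With cheap effort, the same-degree control
  parameterization admits node-scale oscillation of the optimal excitations
  (a known artifact of this transcription family; the original formulation
  avoided it with hp-adaptive meshing, which is out of scope here).  Ringing
  does not disturb the closed loop — only the applied first 5 % of each
  horizon matters — but it limits open-loop collocation-vs-integration
  agreement for cheap-effort instances; the consistency oracle therefore
  uses an effort-dominant instance whose optimal control is smooth.

## Receding-horizon loop

Each iteration solves the horizon OCP from the measured state (measurement
is exact by assumption), applies the first 5 % of the horizon — the
solution's own polynomial control interpolant, integrated with adaptive
RK45 at tolerance 10⁻⁸ — and warm-starts the next solve with the previous
solution shifted by the sampling interval (terminal values held over the
final gap).  A failed solve is retried once from a cold start; a second
failure aborts with the partial record preserved.

Receding-horizon subproblems use a mesh of roughly 40 ms intervals
(K = clip(round(t_ph/0.04), 6, 20), d = 3), so every horizon between 0.2 s
and 0.8 s is resolved comparably; the standalone OCP and the dynamic
optimization default to the fixed K = 25, d = 3 mesh.  The loop stops when
the hand is within 5 mm of the (currently known) target, subject to an
optional minimum time (used by the moving-target and tracking tasks so the
loop survives the target switch/reference duration), or runs to a fixed
duration when errors are to be read at a specific instant.  Records are
sampled on a 1 ms output grid.

A moving point target is frozen at its currently known value for each
horizon — the controller never anticipates a future jump, and learns of a
jump immediately when it happens (no visual-recognition delay, which the
source formulation also excluded).  A tracking reference, by contrast,
stays time-varying inside the horizon.

## Dynamic optimization

The fixed-final-time baseline minimizes ∫ Σ uᵢ² dt alone over [0, t_f]
(default 1.5 s) with a terminal equality on joint angles (inverse
kinematics of the hand target, elbow-flexed-positive branch) and joint
velocities (zero).  Terminal activations are left free: the target position
does not determine them, and constraining them to zero would be an
unwarranted strengthening.  The solve is a homotopy: a tracking-weighted
reach (p = 20, q = 1) provides the initial trajectory, then the pure
minimum-effort problem with the terminal constraint is solved from it.

## Tasks

- **Fixed-target reach**: from the natural posture at rest to a target
  20 cm in −X ("to the left"), run for prediction horizons
  0.2/0.3/0.4/0.5/0.8 s with errors read at 1.5 s.
- **Center-out tracking**: eight targets evenly spaced on a circle around
  the initial hand position, with a quintic (minimum-jerk) straight-line
  reference `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` over 1.5 s by default.  Note a
  geometric inconsistency inherited from the source: with the published
  segment lengths and the hand-position formula, the anterior half of the
  default 20 cm ring lies outside the reachable workspace
  (max reach L1 + L2 = 0.59 m).  `run_task` validates reachability and
  raises for impossible targets; a 10 cm ring is reachable in all eight
  directions.
- **Moving target**: reach toward A (20 cm left); at 1 s the target jumps
  to B.  The default B is 10 cm toward the torso (−Z): the +Z point that
  would mirror it is also outside the workspace.

## Synthetic data

The analysis utilities were designed for motion-capture trajectories and
surface EMG, which cannot be shipped.  `reachmpc.fixtures` generates
stand-ins with known ground truth: minimum-jerk hand paths with Gaussian
capture noise (30 Hz, 2 mm default), and EMG-like signals as 20–450 Hz
band-limited Gaussian noise at 2 kHz amplitude-modulated by bell-shaped
envelopes with per-channel timing offsets plus a tonic floor.  These share
the real signals' spectral structure and modulation depth but none of their
physiology — no motor-unit statistics, no cross-talk, no electrode artifacts
— so passing the fixture-based tests shows the *processing chain* is
correct, not that the model reproduces any subject's recordings.

## Known limitations

- **The horizon-length degradation of reaching accuracy does not emerge at
  the published magnitude.**  With the published inertial and muscle
  constants, the printed cost weights (p = 20, q = 1, hand error in metres)
  and any physiologically proportioned attachment geometry, each muscle
  group can deliver tens of N·m while the 20 cm reach needs only a few:
  the effort term is then so cheap relative to tracking that even a 0.2 s
  prediction horizon drives the hand to the target within a few tenths of a
  second, and the error at 1.5 s is small for *every* horizon instead of
  decaying from ~23 % to ~0.36 % as the horizon grows.  Reproducing that
  published gradient would require an effective mechanical advantage one to
  two orders of magnitude smaller than any straight-line 2–4 cm moment-arm
  geometry provides — plausibly a property of the original tuned geometry,
  which was never published.  The package keeps the physiological defaults
  and reports the discrepancy rather than fitting the geometry to the
  published outcome.
- The closed loop parks within a few millimetres of the target rather than
  converging to zero: near the goal the cost landscape is extremely flat
  and the stall-based solver termination leaves a small residual.  The
  residual is well under the 5 mm stop threshold.
- Open-loop collocation/integration consistency holds at design order only
  for smooth-control instances (see "Control ringing" above).
- The minimum-effort baseline at t_f = 1.5 s operates at excitations of a
  few thousandths — the bang-bang (burst-like) structure of a genuinely
  effort-limited movement does not emerge, and burst timing read from such
  a solution is numerically fragile.
- Sensory noise, plant-model mismatch, the 150 ms visual-recognition delay
  and elastic tendons are all excluded by design, matching the source
  formulation's scope.
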