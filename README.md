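# reachmpc

Predictive simulation of planar human reaching: a two-joint, six-muscle arm
model driven by **nonlinear model predictive control** (NMPC) — receding-
horizon optimal control that re-plans from feedback — and, for comparison,
by fixed-final-time minimum-effort **dynamic optimization** (DO).

The package is aimed at researchers in computational motor control and
biomechanics who want a fully self-contained, optimization-based reaching
simulator: no motion capture or EMG recordings are required to produce hand
trajectories, speed profiles and muscle excitation patterns.

## The model and the controllers

The arm is a planar two-segment linkage (shoulder and elbow revolutes) in a
horizontal plane — gravity-free — actuated by six lumped Hill-type muscle
groups (mono-articular shoulder and elbow flexor/extensor pairs plus a
bi-articular pair) with rigid tendons and first-order
excitation-to-activation dynamics.  The state is
`x = (θ₁, θ₂, θ̇₁, θ̇₂, a₁…a₆) ∈ ℝ¹⁰`, the control the neural excitations
`u ∈ [0, 1]⁶`, and the plant `ẋ = f(x, u)` with
`M(q) q̈ + C(q, q̇) q̇ = R(q) F(a, q, q̇)`.

Each NMPC iteration solves, by Legendre–Gauss–Radau direct collocation,

    min_u  ∫_{t₀}^{t₀+t_ph} [ p ‖ζ(t) − ζ_des(t)‖² + q Σᵢ uᵢ²(t) ] dt
    s.t.   ẋ = f(x, u),   0 ≤ u ≤ 1,

where `ζ(q)` is the hand position and `t_ph` the prediction horizon; the
first 5 % of the optimal excitations is applied to the plant, the state is
re-measured, and the shifted solution warm-starts the next solve.  The DO
baseline instead fixes the final time and terminal state and minimizes
`∫ Σ uᵢ² dt` alone.  A tailored primal-dual interior-point SQP solves the
collocation NLPs (no external NLP library needed).

Three task families are built in: goal-directed reaching to a fixed target
(with a prediction-horizon sweep), center-out tracking of a minimum-jerk
reference, and reaching a target that relocates mid-movement.  Analysis
utilities cover reaching errors, hand-speed profiles, path morphology,
Pearson trajectory/envelope correlation and the standard surface-EMG
conditioning chain, with a seeded synthetic-signal generator for testing.

## Worked example

```bash
python examples/03_fixed_target_nmpc.py
```

```
stopped at t = 0.240 s (12 horizon solves)
residual hand error: 2.46 % of the 20 cm reach
peak hand speed 2.26 m/s at t = 0.060 s; single-peaked profile: True
```

The controller (0.4 s horizon, re-planning every 20 ms) brings the hand
within the 5 mm stop threshold in 0.24 s with a single-peaked speed
profile: for this arm the muscular effort term is cheap relative to the
tracking weight, so the closed loop moves briskly (see
`docs/methods.md` for what this implies compared against effort-limited
movement).  The other examples cover the model itself, a single horizon
solve, the DO baseline, center-out tracking, the moving target and the EMG
pipeline, e.g.

```bash
python examples/07_emg_pipeline.py
```

```
3 synthetic EMG channels at 2000 Hz, carrier band 20-450 Hz
  emg_ch1: envelope-vs-truth Pearson r = 0.993
  emg_ch2: envelope-vs-truth Pearson r = 0.993
  emg_ch3: envelope-vs-truth Pearson r = 0.986
noisy capture trajectory vs ground truth: r = 1.0000
```

A thin CLI wraps the task runners:

```bash
reachmpc nmpc --horizon 0.8 --p 20 --q 1 --target-dx -0.20 --duration 1.5 --out runs/fixed
reachmpc do --tf 1.5 --target-dx -0.20 --out runs/do
reachmpc sweep --horizons 0.2,0.4,0.8 --out runs/sweep.csv
```

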