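# Methods

## The modality transformation

`pose2imu` converts 6-DoF pose streams from tracked VR hand controllers —
world-frame position `p(t)` and body-to-world unit quaternion orientation
`o(t)`, uniformly sampled — into the signals an inertial measurement unit
rigidly attached to the controller would report:

    v(t) = vec( o*(t) ⊗ p'(t)  ⊗ o(t) )          body-frame velocity
    a(t) = vec( o*(t) ⊗ p''(t) ⊗ o(t) )          body-frame acceleration
    ω(t) = 2 M(o(t)) o'(t) = 2 vec( o*(t) ⊗ o'(t) )   body-frame angular rate

where `⊗` is the Hamilton product, `*` the quaternion conjugate, and `'` the
forward difference over the sample period.  `M(o)` is the 3×4 body-rate
matrix

    M(o) = [[-x,  w,  z, -y],
            [-y, -z,  w,  x],
            [-z,  y, -x,  w]]

acting on `(o'_w, o'_x, o'_y, o'_z)`.  The matrix route and the
conjugate-product route are algebraically identical; both are implemented and
their agreement (to 1e-12) is asserted in the tests, which pins down the sign
convention: `ω` is the **body-frame** angular velocity.

Why body frame matters: the sandwich `o* ⊗ · ⊗ o` makes every derived channel
invariant to a rigid re-orientation of the world (rotate all positions and
left-compose all orientations with a fixed rotation — nothing changes, to
1e-9).  World-frame position and Euler-angle channels have no such
invariance, and that asymmetry is precisely what the transformation exploits
for cross-session biometrics: where a subject stands and faces changes from
day to day; how they move does not.

Numerical choices:

* **Forward differences** (not central), applied twice for `p''`, with the
  last element duplicated so all series keep the input length.  The two
  end-padded samples are excluded from closed-form error checks.  The scheme
  is first order: for a constant-rate rotation the `ω` error shrinks at least
  linearly as the sample rate doubles (asserted at 30/60/120 Hz).
* **Quaternion sign continuity** is enforced before any differencing: `q` and
  `-q` encode the same rotation, and recordings may flip sign between
  samples; a naive difference across a flip is catastrophically wrong.  The
  correction keeps the first sample and flips each subsequent one whenever
  that makes consecutive dot products non-negative.
* **No gravity** in the synthetic accelerometer: the transform models
  kinematic acceleration.  An opt-in flag (`add_gravity`) subtracts
  body-frame gravity for users who want specific-force (accelerometer)
  semantics.
* **Conditioning** is a zero-phase 4th-order Butterworth low-pass
  (`scipy.signal.sosfiltfilt`), applied per channel to acceleration and
  angular velocity after the transform, at 3 or 6 Hz typically.  Zero-phase
  filtering avoids time-shifting biometric features; the forward-backward
  pass puts the half-amplitude point exactly at the nominal cutoff.
* **Uneven sampling is rejected**, not silently resampled (1e-6 s jitter
  tolerance on the time column); quaternions within 1e-3 of unit norm are
  re-normalized on input, anything further is an error.

Euler angles use the intrinsic Z-Y-X (yaw-pitch-roll) convention — the
natural choice for yaw-dominant controller data; at the pitch singularity
(|pitch| = 90°) the yaw/roll split is resolved by fixing roll = 0.  Assembled
EULER features are deliberately left wrapped: the ±180° discontinuity is the
phenomenon under study, and unwrapping would erase it.

## The synthetic gesture corpus

The generator emulates a VR basketball-throw corpus: one dominant reach along
world X with a minimum-jerk profile `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`, a
subject-specific wrist sweep about a near-+Y axis, a still tail after the
movement completes, trial-level tracking noise, and two between-day effects.
Subject identity lives in the template parameters; trials differ by noise;
days differ by template drift and placement.

Default study conditions (41 subjects × 10 trials × 2 days, 3 s at 45 Hz =
135 frames) and per-subject parameter distributions:

| parameter | distribution | role |
|---|---|---|
| reach amplitude | N(0.9, 0.1²) m, > 0.3 | forward extent |
| movement duration | N(1.4, 0.15²) s in (0.5, 2.5) | tempo |
| velocity-peak fraction | 0.3 + 0.4·Beta(2,2) | skew of the profile |
| wrist sweep angle | N(2.44, 0.26²) rad in (1.5, 3.2) | ≈140°±15° wrist rotation |
| wrist axis | +Y tilted 8–25°, azimuth constrained (below) | sweep plane |
| lateral curvature | N(0, 0.05²) m | sideways bow |
| base yaw | N(π−0.12, 0.02²) rad, truncated | facing, near the ±π wrap |
| resting yaw offset | U(0.05, 0.08) rad past +π | wrap dwell after the throw |

Asymmetry of the velocity profile uses the monotone warp
`w(τ) = τ + a·τ(1−τ)` with `a` set so the velocity peak lands at the
subject's peak fraction; unlike a power-law warp it has finite slope at both
ends, so acceleration stays bounded at movement onset.  `(duration, peak
fraction, sweep)` are redrawn jointly until the peak angular acceleration
stays under 40 rad/s² — a physiological smoothness envelope that also keeps
per-sample gyroscope steps below 1 rad/s at 45 Hz.

**The Euler-wrap construction.**  Left-composing a Z rotation adds exactly to
the intrinsic Z-Y-X yaw, so the trial's yaw channel is the base progression
plus the wrist sweep's own yaw contribution.  Two structural choices make the
wrap discontinuity a guaranteed, controllable property of every trial:

1. Wrist axes whose sweep path brings the canonical pitch within 0.2 rad of
   ±90° are rejected and redrawn — near that singularity the Euler
   decomposition branch-flips by ±π, which can cancel the ±2π wrap jump and
   also makes the sweep's yaw contribution non-smooth.  Of the two opposite
   tilt azimuths, the one needing the smaller compensating progression is
   kept.
2. The yaw progression amplitude is set so the hand *settles* 0.05–0.08 rad
   past +π.  The yaw channel therefore crosses the boundary during the throw
   (a single consecutive-sample jump of ≈2π), and in the still tail it sits
   at the boundary, where orientation noise flips the wrapped value by ≈2π at
   random times — the flickering Euler pathology familiar from real
   recordings.  The underlying rotation path is smooth throughout, so the
   gyroscope sees none of this.

**Noise and day effects.**  Positional jitter is 2 mm, broadband (white noise
low-passed at 9 Hz): most of its power sits above the movement band, so the
3/6 Hz conditioning of derived signals actually removes it, as it does for
real tracking error.  Orientation jitter is 0.02 rad, smoothed at 3 Hz so the
angular acceleration it injects cannot spoil gyroscope smoothness.  Between
days, (a) the motion template drifts by 5% (relative, on amplitude, duration,
sweep, axis), and (b) the subject's *placement* changes: a world-frame yaw
rotation (σ = 0.02 rad, clipped at ±0.04) and position offset (σ = 3 cm per
axis), constant within a day.  Placement is the key cross-day mechanism:
body-frame ACC/GYRO are exactly invariant to it, world-frame POS and EULER
are not, so the baseline modality generalizes worse across days for a
documented, controllable reason.

What the generator does **not** model: device-specific biomechanics (device
is a manifest label only), sensor bias/scale-factor error models, gravity
leakage, magnetometer channels, or uneven sampling.  Passing tests therefore
show that the pipeline is correct and that the modality effect appears under
the stated mechanism — not that effect sizes transfer to any particular real
corpus.

## Classifiers

Three 1-D CNN families over per-trial arrays (`length × channels`), built on
an in-repo numpy layer engine with hand-derived gradients (deterministic
given a seed):

* `vanilla_cnn` — conv blocks of 64/128/128 filters (kernels 7/5/3, each
  ReLU + max-pool 2) → global average pooling → softmax.  Input 128×6 for
  stacked modality pairs.
* `attention_cnn` — same trunk, with additive temporal attention pooling
  (single-unit score per time step, softmax over time) instead of the global
  average.
* `multi_input_cnn` — two branches of 32/64/64 filters with **equal kernel
  counts**, so both modalities contribute equally many features at the
  decision stage; branch embeddings (global-average pooled) are concatenated
  into a dense-128 head.  Inputs 100×3 per branch.

Exact layer dimensions are package choices (sized for single-CPU training)
and are overridable through `ModelSpec`.  Training follows the reference
protocol: categorical cross-entropy, Adam at learning rate 0.01, a fixed
epoch budget (default 300) with no early stopping, no weight decay and no
scheduler, batch size 32, repeated over independently seeded initialisations
(default 20) to average out initialisation luck.  Rows are canonically
ordered by a content hash before shuffling, so training is invariant to the
incoming trial order; all randomness derives from the explicit seed.

## Evaluation protocol

Train on every day-1 trial, test on every day-2 trial of the same subjects
(`cross_day_split`; swap-day supported).  Features are z-scored per channel
with statistics fit on the training day only — perturbing test-day data
provably leaves training features untouched.  Recordings are resampled to the
model input length by per-channel linear interpolation over the full time
span.

Metrics: macro F1 (unweighted over classes; classes are balanced) and
One-vs-Rest AUC/FAR/FRR.  AUC per class uses the softmax column against
binary membership; FAR and FRR come from the argmax decision, ties broken
toward the lowest class index.  For balanced test sets the argmax definition
implies `mean FAR = mean FRR/(K−1)` *exactly* (total false positives equal
total false negatives, and each class's negative pool is (K−1)·n) — the
published Multi-Input tables of the motivating study satisfy this identity to
their printed precision, which is the evidence for the argmax definition.
`mean FRR = 1 − micro-accuracy` for balanced sets, also asserted.  Grid runs
(`run_experiment_grid`) derive per-cell and per-repetition seeds from one
master seed and record cell failures as data rather than aborting.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run a scaled-down study: 10 subjects × 10 trials × 2 days
at 45 Hz, multi-input CNN, 60 epochs, 1–3 repetitions per cell, 5 master
seeds for the modality comparison; transform and metric identities use 100
seeded sequences and 1000 random confusion settings.  These sizes are package
choices that keep a full run in minutes on one CPU while leaving the
qualitative results stable across seeds.

## Known limitations

* The forward-difference scheme is first order; at 45 Hz the discretisation
  error in ACC is visible (the paper's pipeline shares this property).
* FAR/FRR are argmax-based identification metrics; no score-threshold DET/EER
  analysis is provided.
* The learning rate 0.01 for hundreds of epochs is aggressive for the small
  corpus sizes the generator produces; it is kept as the reference protocol
  and is overridable in `TrainConfig`.
* The loader for the motivating external corpus is a documented adapter stub
  (`datasets_io.load_miller_corpus`); converting that corpus's native layout
  to the pose CSV dialect is left to users with a local copy.
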