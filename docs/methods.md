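# Methods

`gaitstrain` estimates lower-body joint angles during treadmill running from
fabric-mounted piezoresistive strain sensors. It implements the complete
methodology — sensor-placement optimization, signal preprocessing, a windowed
CNN regressor, and cross-validated evaluation — and, because no public
recording of this kind of garment-sensor running data exists, a synthetic
gait-and-sensor simulator that provides controlled ground truth for every
stage. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## The synthetic study conditions

### Joint-angle trajectories

Six channels are simulated in a fixed order: hip sagittal, hip frontal, hip
transverse, knee sagittal, ankle sagittal, ankle frontal. Each channel is a
truncated Fourier series (three harmonics) over the stride cycle,

    angle_c(t) = mean_c + a_c * s(v) * sum_h A_{c,h} sin((h+1) phi(t) + psi_{c,h}),

with stride phase `phi(t) = 2 pi f(v) t + phi_0`. Stride frequency
`f(v) = (cadence_base + 2.5 (v - 10)) / 60` Hz increases strictly with
treadmill speed `v` (km/h), and the amplitude factor
`s(v) = 1 + 0.03 (v - 10)` grows mildly with speed. Per-runner parameters
(`cadence_base ~ 80 +/- 3` strides/min, per-channel amplitude scale
`~ N(1, 0.08)`, phase offsets `~ N(0, 0.15)` rad) model inter-individual
variation; a small per-trial amplitude jitter (2%) and random initial phase
keep repeats from being clones. Default ranges of motion (hip sagittal
~45-50°, knee sagittal ~70-90°, ankle sagittal ~45°, non-sagittal channels
~10-15°) are literature-plausible values for running; no public per-joint
table exists for this protocol, so they are design choices, chosen once.
Reference angles are low-pass filtered with a zero-phase (forward-backward)
4th-order Butterworth filter at 6 Hz, the standard conditioning for optical
reference kinematics; zero-phase filtering is used because reference
kinematics are computed offline where phase distortion is avoidable.

The default protocol mirrors a realistic treadmill session: 3 repeats x 5
speeds (8-12 km/h) x 60 s at 100 Hz = 15 one-minute trials and 90,000
frames per runner.

### Sensor voltages

Each of the nine sensors (four pelvis, two knee, three ankle) sees a latent
strain-like drive `e = 0.35 * (z @ w)`, where `z` are range-normalized
angles and `w` a sensor-specific loading vector: pelvis sensors load mainly
on the three hip channels, knee sensors on the knee, ankle sensors on the
ankle channels, with small cross-talk. The voltage is

    V = V0 * (1 + gain * sat(e)) + N(0, sigma^2),

with `sat(e) = 0.3 tanh(e / 0.3)`: the fiber sensors are linear below 30%
strain, so the default drive (|e| <~ 0.2) stays in the near-linear regime
with mild compressive nonlinearity. `saturation="linear"` switches to an
exactly linear map for recovery oracles. Defaults: baseline `V0 ~ U(1.2,
1.8)` V per sensor, gain `~ N(1, 0.1)`, noise `sigma = 4` mV, drift off
(the real sensors hold a consistent signal over hours). The loading matrix
lives on the `SensorModel`, so ground truth is always recoverable in tests.

### Marker-grid strain field

The placement study is emulated with a 5 x 10 marker grid (spacing 4.4 cm:
the garment stretches when worn, so worn neighbor distances exceed the 4 cm
print spacing). Four designated vertical top-edge pairs are informative:
the upper marker of each translates along the pair axis by an affine
function of a hip-angle mix (three channel-dominant mixes plus one balanced
mix, so the full 3-D hip state is linearly identifiable from the four
positions), peaking at 15% strain. All other markers move in-plane with a
fixed spatial contrast pattern (a checkerboard of moving vs anchored
markers with mild deterministic amplitude variation) driven by one smooth,
gait-independent signal per trial rescaled to exactly [-1, 1]. This makes a
realistic share of uninformative neighbor pairs strain reproducibly past
the 10% placement rule in every trial (the candidate pool in a real
placement study is mostly positions that strain but carry little joint
information), while the geometric "shadows" of the informative markers
(diagonal neighbors, which inherit ~70% of the displacement projected onto
a longer baseline, ~8% strain) stay below the filter. Small white marker
jitter (0.2 mm) models optical tracking noise.

What the simulator does **not** model: ground-reaction forces, bilateral
gait, cloth physics (the wrinkle clamp is the only fabric nonlinearity),
sensor hysteresis and long-term drift, soft-tissue artifact, and
distribution shift between runners beyond smooth amplitude/phase/gain
variation. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under controlled conditions — not hardware
performance on human data.

## Strain field and candidate filtering

Candidate sensor positions are all neighboring marker pairs in vertical,
horizontal and both diagonal orientations (an interior marker participates
in 8 pairs). Strain is `(max(L, 4 cm) - L0) / L0` with `L` the 3-D marker
distance and `L0` the neutral standing distance: distances below 4 cm mean
the fabric has wrinkled and carry no mechanical signal, so they are
clamped, which bounds every strain below by `(4 - L0) / L0`. Candidates
must reach 10% peak strain (inclusive: "a minimum of 10%" reads as >=)
during running; a candidate must pass in **every** trial and speed of the
placement dataset — the strictest reading, which avoids speed-dependent
candidate sets. The fixed 40-position pool used by the optimizer is the 40
surviving pairs with the highest worst-case (minimum over trials) peak
strain; distances are Euclidean with no surface-geodesic correction, since
marker distances are themselves the proxy for fabric strain.

## Placement optimization

The objective is wrapper-style: for a candidate subset, fit OLS (with
intercept) from the subset's strain columns to the three hip-angle planes
on all runners but one, score held-out R^2 per plane, and average over the
three planes within each fold, then over folds (the alternative aggregation
order is configurable; the default averages the 3-plane mean across folds).
`PrecomputedLOPO` evaluates the identical normal equations from
per-participant sufficient statistics (Gram and cross-moment matrices), so
the optimizers can score thousands of subsets cheaply; equivalence with the
direct least-squares route is asserted to 1e-9 in tests. Rank-deficient
designs fall back to the pseudoinverse and are flagged.

Sequential forward selection adds, at each step, the candidate that
maximizes the objective given the current subset (ties break to the lowest
index for determinism); subsets are nested by construction. The genetic
algorithm uses binary chromosomes of fixed cardinality k over the
40-position pool: population 30, roulette-wheel mating pool of 15, balanced
one-point crossover with probability 0.8 (cut points are valid only where
both parents' prefixes contain equal ones-counts, so children conserve
cardinality; if no interior point qualifies the parents pass through
unchanged), interchange mutation with probability 0.5 per offspring (one
random 1-gene swapped with one random 0-gene), and elitism of the two best
individuals. Because out-of-sample R^2 can be negative, roulette
probabilities use fitness shifted by its minimum plus a 1e-6 floor, with a
uniform fallback when all fitnesses tie. Defaults run up to 150 generations
with early stopping after 40 stagnant generations: with
cardinality-conserving operators and a 30-individual population, runs
routinely sit on near-optimal plateaus for longer than a few generations
before a mutation escapes, and objective evaluations are cheap enough that
the larger budget costs seconds. Elites are copied unmodified and remain
eligible as parents.

## Preprocessing

Fixed order: relative voltage `(V - V0)/V0` against the static-standing
baseline -> per-channel z-scoring -> Savitzky-Golay smoothing (window 31,
order 5) -> derivative channels -> sliding windows. Standardization
statistics are computed within a partition only; the test partition is
standardized with its own statistics (deliberately, matching the
experimental procedure this package reproduces) and a conventional
train-stats mode is available via the `stats=` argument. Derivatives are
central differences scaled by the sample rate, with edge frames replicating
their nearest interior value; they are computed after smoothing to avoid
amplifying noise, and on the full trial before windowing so window edges
see no boundary artifacts. Each window is 60 frames (600 ms at 100 Hz) x 27
channels ordered [9 raw, 9 first-derivative, 9 second-derivative]; the
target is the angle vector at the window's **last** frame (causal
alignment, compatible with real-time use); stride is configurable (default
1; the packaged experiments use 4 to keep training sets small). Windows
never span trial boundaries. Zero-variance channels get their sd floored at
1e-8 and are flagged.

## CNN regressor

Four convolutional layers with kernel (3, 1) — kernels move along the time
axis only — followed by a dense head and a linear output of 6 (person-
specific) or 3 sagittal (cross-person) angles. All hidden layers are ReLU;
all weights are Xavier-uniform initialized; no pooling (temporal extent
shrinks only through valid convolutions). Defaults: conv filters (32, 32,
64, 64), one dense layer of 128 — modest capacity suited to a 60 x 27
input; the exact widths are free parameters of the architecture family.
Training uses mini-batch Adam, batch 128, exactly 10 epochs. The
person-specific loss is the plain multi-output MSE
`(1/(6N)) sum_i sum_j (yhat_ij - y_ij)^2`; the cross-person loss weights
the three sagittal joints as `2*MSE_hip + 1*MSE_knee + 5*MSE_ankle`,
reflecting that hip and ankle are harder to estimate on an unseen person.
Cross-person training first draws one bootstrap subsample of 60% of the
training windows with replacement (drawn once per run, as in bagging, not
per epoch), which regularizes against memorizing the training runners.

The network is implemented directly on numpy: im2col convolutions, manual
backpropagation (gradients verified against finite differences to ~1e-8),
and Adam with beta = (0.9, 0.999), eps = 1e-8. At this scale a deep-
learning framework adds nothing, and a self-contained graph keeps CPU
training bit-reproducible from a single seed.

Two numerical choices matter for the fixed 10-epoch budget. The output
bias is initialized to the training-target channel means (the standard
init-score trick), so no epochs are spent walking the output head toward
angle offsets of tens of degrees. And the default learning rate is 5e-3
rather than the more conventional 1e-3: targets are in degrees with ranges
up to ~90°, and at 1e-3 Adam cannot traverse that output scale within 10
epochs at the packaged problem sizes. Both are defaults, not constraints.

## Evaluation

Person-specific: per runner, 3-fold CV where fold i contains repeat i of
every speed, so each fold spans the full speed range (this requires exactly
three repeats per speed; other designs raise an error). Cross-person:
leave-one-participant-out. Metrics per joint: R^2 computed over the
concatenated test predictions within a fold, RMSE in degrees, and NRMSE =
100 * RMSE / (max - min) of the test-fold reference — range normalization
is a convention choice (the quantity has no universal definition), selected
because it is the one consistent with how NRMSE values in this literature
relate to reported RMSE and joint ranges of motion. Fold-level metrics are
aggregated as mean (sd). Per-speed tables reuse the all-speed-trained
model and stratify its test predictions by speed; the pooled squared RMSE
equals the frame-weighted mean of per-speed squared RMSEs (asserted as an
identity in tests).

## Problem sizes in the packaged experiments

The packaged experiments (test suite and `scripts/acceptance.py`) run the
full pipeline at reduced scale, chosen as the smallest structurally
complete designs: optimizer benchmarks on 10-14 candidates (where the
exhaustive optimum is enumerable); placement recovery with 5 virtual
runners x 3 speeds x 10 s against the 40-candidate pool; the person-
specific CNN experiment with 4 virtual runners x 3 speeds x 3 repeats x
20 s (3 minutes of running per person) at window stride 4; and a 3-runner
cross-person experiment. Margins at these sizes are wide (R^2 >= 0.97 on
sagittal channels against a 0.90 bar), so the reduction does not sit near
any decision boundary.

## Known limitations

* The simulator's angle-to-voltage map is close to linear by design; it
  shows the pipeline recovers the mapping, not that a CNN beats a linear
  model on real sensors (hysteresis and rate-dependence, which motivate
  the CNN, are not simulated).
* Test-partition self-standardization assumes the test partition is long
  enough for stable statistics; very short test sets should use the
  train-stats mode.
* The GA's roulette selection applies weak pressure when fitness spreads
  are tiny; the generous generation budget compensates at these problem
  sizes but large candidate pools may need selection-scheme variants.
* NRMSE depends on the test fold's observed range of motion, so values are
  not comparable across folds with very different ranges.
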