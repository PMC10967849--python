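# Methods

`imugait` implements the sensing-and-recognition chain of a belt-driven
soft hip-assist exoskeleton: five inertial measurement units (waist, both
thighs, both feet; 3-axis gyroscope + 3-axis accelerometer each, 30
channels at 200 Hz) feed a motion-state recognizer and a gait-phase
recognizer, whose outputs anchor a hip-flexion assistance-force pulse in
time. This note records the models, the parameters that matter, what the
synthetic data does and does not emulate, and the numerical choices.

## Gait events and phases

A gait cycle carries three events per leg — heel strike (HS), toe off
(TO) and the instant of maximum hip flexion (HMax). With the legs half a
cycle out of phase the six events recur in a fixed chronology:

    L-HS → R-TO → R-HMax → R-HS → L-TO → L-HMax → (next L-HS)

Detection is rule-based and per-channel:

* **HS** — falling zero crossing of the foot gyro Z channel (the foot's
  angular velocity decreases rapidly through zero at ground contact).
  The event index is the first non-positive sample; crossings closer than
  a refractory window (default: a quarter cycle, estimated from the
  channel's autocorrelation) are treated as chatter, first kept.
* **TO** — negative trough of the same channel (maximum plantar-flexion
  rate), located by peak detection with prominence at least 3× the
  estimated channel noise (median absolute deviation of first
  differences, scaled by 1.4826/√2). Boundary extrema, which have no
  two-sided neighborhood, are not reported.
* **HMax** — falling zero crossing of the *thigh* gyro Z channel: the
  thigh's angular velocity vanishes at the hip-angle maximum. The thigh
  gyro stands in for a hip-angle maximum because only inertial signals
  are available online; optical motion capture is out of scope.

**Timeline merging.** Per-channel detections are merged into one
chronology-consistent timeline by a scored dynamic program: every kept
event scores 1; consecutive kept events must have strictly increasing
indices and advance the cycle by 1–4 classes; any non-unit advance (a
"resync" across a missed detection) costs 2.5. The penalty makes a lone
spurious detection unprofitable — wedging it between two correctly
ordered events breaks the unit chain twice, costing 5 to gain 1 — while a
genuine miss is bridged by a single paid resync that buys the whole
remaining chain. A plain greedy keep-if-order-consistent rule was
rejected: with gap tolerance, spurious insertions are themselves
order-consistent and a greedy pass retains them. Ties resolve to the
earliest events.

**Order validation** tolerates forward gaps of up to four classes
(missed detections) and reports a repeated class or a one-step regression
as a violation. Validation is deliberately laxer than merging: a merged
timeline should be parsimonious, but a timeline with holes is still
chronologically valid.

**Phase labels.** Each sample between two consecutive events carries the
earlier event's class, giving a 6-class per-sample labeling; samples
before the first event take the class cyclically preceding it.

## Motion-state recognition (binary-tree RBF-SVM)

Ten locomotion states — standing (SD), level walking (LW), stairs up/down
(US/DS), slopes up/down (USL/DSL), turning left/right (TL/TR), steering
left/right (LS/RS) — are separated by a binary tree of soft-margin RBF
SVMs. Each internal node splits its class subset into two halves
(balanced split over the fixed order SD, LW, US, DS, USL, DSL, TL, TR,
LS, RS; 9 internal nodes, depth 4 for ten classes); prediction descends
by decision sign (≥ 0 takes the first branch — the deterministic tie
rule). The input is the instantaneous standardized 30-channel vector.

Per node, the decision function is the kernel expansion
f(x) = Σᵢ λᵢ yᵢ K(xᵢ, x) + b with K(a,b) = exp(−γ‖a−b‖²), dual
coefficients box-bounded in [0, C]. Defaults: **C = 2**, **γ = "scale"**
= 1/(30 · Var(X)), resolved per node on that node's training subset. The
quadratic programs are solved by scikit-learn's SMO-based `SVC`; the
package's own contribution is the tree composition, the γ resolution and
the exposed, oracle-checkable kernel expansion. The balanced in-order
topology is a package choice; any topology whose leaves partition the
class set is accepted.

## Gait-phase recognition (LSTM)

The phase recognizer is a standard LSTM cell — forget, input and output
gates and a cell state, all acting on the concatenation [h_{t−1}, x_t] —
unrolled over a window of **n = 5** consecutive standardized samples,
followed by a fully connected ReLU layer and a 6-way softmax. The window
target is its **last** sample's phase, so a prediction at time t uses
only samples t−4…t (causal, usable online). Reference capacity is 128
LSTM units and a 32-unit FC layer trained for 200 epochs in batches
of 64; the test suite and acceptance script use a desk-scale
configuration (32 units, 30 epochs) that trains in under a minute on one
CPU and reaches the same qualitative behavior.

The implementation is pure NumPy: forward pass, backpropagation through
time and an Adam optimizer (categorical cross-entropy, learning rate
10⁻³, Glorot-uniform initialization, zero biases), all driven by a single
seed so training is exactly reproducible. Correctness is pinned by
elementwise oracles on the gate equations and a numerical gradient check.

**Standardization.** Both recognizers consume per-channel z-scored
signals; statistics are fitted on training subjects only and reused
unchanged for test data (no leakage). Z-scoring is used rather than
min-max scaling: it is the standard choice for roughly stationary
oscillatory signals and is what "standardized" conventionally means.

## Assistance planning

Hip-flexion assistance imitates the rectus femoris: a force pulse

    F(t) = A · sin(π t / Ta + α) · sin(π t / Ta) + f,   t ∈ [0, Ta]

starting at TO, ending at the next ipsilateral HS (Ta = swing period),
clamped at zero from below and identically zero outside the window. The
product-of-sinusoids reading of the profile is the default — it vanishes
at the window start and gives a single tunable interior peak; a simple
single-sinusoid form A·sin(π t/Ta + α) + f is available behind
`form="simple"`. The phase shift has a closed form: the interior
extremum lies where sin(2π t/Ta + α) = 0, so placing the peak at fraction
s\* of the swing gives **α = π(1 − 2 s\*)**; the solution is verified
against a 10⁻⁴-resolution grid search in the tests. Defaults **A = 40 N**
(a moderate assistance magnitude), **f = 2 N** (just enough pretension to
keep the transmission belts taut).

Assist times for the upcoming cycle are predicted by dead reckoning from
the previous one: each event is expected one (previous) cycle period
after its last occurrence, so under constant cadence the prediction is
exact and under cadence drift the error is bounded by the per-cycle
period change. Profiles are gated by motion state: a cycle whose
majority state is not level walking gets a zero-force profile — the
safety posture for stairs, slopes, turning and standing. The first cycle
of a bout, which has no predecessor, is anchored on its own events.

## Synthetic gait generator

The generator produces two-leg 30-channel streams with exact embedded
ground truth. It is **not** a biomechanical simulation; waveforms are
shaped only to carry the structure the detectors key on:

* foot gyro Z: one steep falling zero crossing per cycle exactly at HS
  (slope ≈ 0.24 rad/s per sample at 200 Hz), a sharp V-notch trough
  exactly at TO (depth 3.5 rad/s), a single positive swing peak
  (6 rad/s), and a slightly negative stance plateau with no other
  falling crossings. Steepness and cusp sharpness are what keep event
  localization within ±2 samples under noise;
* thigh gyro Z: a 4 rad/s sinusoid whose falling zero crossing lies at
  HMax;
* the other channels: smooth periodic textures, with gravity (9.81 m/s²)
  as a static component on the vertical accelerometer axes.

Default event placement: own-leg HS at fraction 0.00, TO at 0.60, HMax
at 0.85 of the cycle, legs offset by 0.5 — standard level-walking
phenomenology, and the resulting phase durations (10/25/15/10/25/15% of
the cycle) match the proportions of the packaged phase-count table.
Cycle period 1 s, 200 Hz sampling, additive white Gaussian sensor noise
(σ = 0.05 rad/s gyro, 0.1 m/s² accelerometer).

States are distinguished by per-state channel gains and constant offsets
on physically suggestive channels: turning/steering bias the waist yaw
rate (±1.5 / ±0.7 rad/s), stairs and slopes bias the waist accelerometer
axes (±0.8 m/s²) and scale the leg gyro gains, level walking carries a
small forward-acceleration bias (0.35 m/s²), and standing scales all
dynamics to 1%. Offsets are sized so every pair of states differs in at
least one channel by well over 3× the sensor noise — the separability
contract that makes the 10 classes learnable by construction. Subjects
differ by ±10% multiplicative jitter on cycle period and channel gains;
per-stream noise seeds derive from one base seed by a fixed counter
scheme (base + 100000·subject + 1000·state-index), so any subset of
subjects or states reproduces bit-identically in isolation.

**What passing tests do and do not show.** The generator has constant
within-bout cadence, stationary noise, no soft-tissue artifact, no sensor
drift or mounting variation, and state signatures that are cleanly
separable by design. High held-out accuracies on this data demonstrate
that the pipeline is implemented correctly and that the recognizers can
exploit the intended signal structure — they are not evidence about
performance on human recordings, where the corresponding reference
accuracies were measured on 25 instrumented subjects.

## Evaluation conventions

Confusion matrices index (predicted row, true column) and are normalized
**by column** (true-class support), so every supported column sums to 1;
zero-support columns stay zero and are flagged. F1 is macro-averaged;
classes with no true and no predicted samples are excluded from the mean.
MCC uses the multiclass covariance form over the confusion counts (it
reduces to the binary MCC for two classes; a zero denominator — e.g. a
single predicted class — yields 0 by convention). Splits and five-fold
cross-validation are grouped by subject: no subject's samples ever span
the train/test boundary, so reported accuracies are subject-generalization
accuracies.

## Problem sizes

The test suite and acceptance script run, per invocation: event recovery
on 50 cycles (300 events) at noise σ = 0.05 rad/s; the 10-state SVM on 5
synthetic subjects × 6 cycles per state (train 4, test 1, training
samples thinned 5×); the LSTM on 5 subjects × 20 level-walking cycles
(≈ 16.5 k training windows, hidden 32, 30 epochs); and a five-fold
subject-grouped CV of the SVM. These sizes keep a full run in the
low minutes on one CPU while leaving all thresholds comfortably cleared.

## Known limitations

* The LSTM trains on CPU in NumPy; it is sized for the desk-scale
  configuration and would be slow at the full reference capacity on
  large corpora.
* `min_separation` debouncing keeps the first crossing of a chatter
  cluster, which can bias detections one sample early at very low
  signal-to-noise.
* An HS event at sample 0 of a bout has no preceding sample and is
  undetectable by the crossing rule; recovery rates count it as missed.
* The timeline merger assumes at most sporadic detector failures; long
  dropouts (many consecutive missed events) are bridged as a single
  resync and the intervening candidates are dropped.
* Assistance-time prediction is one-step dead reckoning; it does not
  model cadence trends or accelerations.
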