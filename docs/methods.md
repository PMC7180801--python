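# Methods

This note documents the models, conventions, numerical choices and known
limitations of `uplimb`. It is the reference for *why* the package computes
what it computes; the README covers *how* to run it.

## Problem setting

A single consumer depth sensor reports a 3D skeleton (~30 Hz) from which
upper-limb joint angles can be computed, but the skeleton suffers large,
plane-dependent systematic errors — worst for transverse-plane (axial
rotation) angles — that make the raw angles clinically unusable. A
marker-based optical system (~100 Hz) with an upper-limb marker set provides
the gold standard. The package computes angles from both streams, aligns
them, and trains a recurrent network that maps the depth-sensor angle
sequences toward the gold-standard ones, evaluated subject-wise so reported
performance is always on unseen subjects.

## Joint angle models

Both models express each segment relative to its proximal segment and
decompose the relative rotation with the mobile z-x-y Euler sequence

    R = Rz(FE) · Rx(AA) · Ry(IE)

so that flexion/extension (FE) is the rotation about the proximal segment's
z-axis, adduction/abduction (AA) about the rotated x-axis and
internal/external rotation (IE) about the twice-rotated y-axis. The closed
form gives the extraction

    AA = asin(R[2,1]),  IE = atan2(-R[2,0], R[2,2]),  FE = atan2(-R[0,1], R[1,1]).

Within 1° of AA = ±90° the outer angles become degenerate (gimbal lock);
the implementation then sets IE := 0 and assigns the observable sum to
FE = atan2(R[1,0], R[0,0]), and flags the sample. The compose/decompose
round trip is exact to < 1e-9° for |AA| ≤ 85° (property-tested on a
31×31×31 grid).

**Depth-sensor model.** Thorax: y from SpineMid to SpineShoulder,
z ⟂ {y, ShoulderLeft→ShoulderRight}, x = y×z, origin SpineShoulder.
Upper arm: origin ElbowRight, y from elbow to shoulder, z ⟂ {y,
elbow→wrist}, x = y×z. Elbow flexion is the angle between the upper-arm
long axis and the elbow→wrist vector; the default `flexion` convention
reports 0° at full extension (180° − acos), because reported
target-achievement elbow angles of ~145° at deep flexion are only consistent
with a flexion-zero-at-extension convention. The literal acos value is
available as `raw-acos`.

**Marker-based model.** Thorax: origin mid(C7, CLAV), y from mid(T10, STRN)
up to mid(C7, CLAV), z along the normal of the (T10, C7, CLAV) plane with
the lateral sign chosen toward the shoulder joint center (the protocol
states "pointing laterally" only qualitatively; the sign rule here is a
package convention). Shoulder center = centroid of the available shoulder
markers (PSH, ASH, plus ACR when present; at least two required), elbow
center = mid(EM, EL), wrist center = mid(RS, US). The upper-arm frame uses
the same construction as the depth-sensor model applied to the joint
centers. Forearm: origin at the wrist center, y from wrist to elbow,
x ⟂ {y, US→RS} with the anterior sign fixed against the thorax x-axis at
the first frame and temporal continuity afterwards; elbow angles
(flexion/extension, varus/valgus, internal/external rotation) come from the
same z-x-y extractor applied to the upper-arm → forearm rotation.
Varus/valgus and forearm rotation are computed but excluded from the
4-channel waveform used everywhere downstream.

**CAST.** Elbow and wrist anatomical markers are removed for dynamic
trials; their positions are reconstructed from rigid 3-marker clusters on
the upper arm (PUA, carrying EM/EL) and forearm (DUA, carrying RS/US). A
static trial defines each landmark's constant coordinates in its cluster's
technical frame (marker1 = origin, x toward marker2, z ⟂ cluster plane,
averaged over static frames); dynamic frames rebuild the technical frames
and map the constants back. Reconstruction is exact (≤ 1e-9 mm) under rigid
motion and degrades ∝ marker noise / √frames under jitter; any consistent
cluster-frame convention yields identical reconstructions.

**Singular poses.** With the elbow fully extended the upper-arm z-axis
(y × elbow→wrist) is undefined. In trajectory mode the last valid z-axis is
carried forward (backward for a leading gap) and the frame indices are
recorded in the waveform metadata; a single frame in isolation raises a
singular-geometry error; a trial with more than 20% singular frames is
rejected as unusable. Temporal carry-forward mirrors how optical pipelines
ride through instantaneous singularities.

Angles are unwrapped per channel (nearest-revolution continuity, first
frame anchored to (−180°, 180°]). All angle outputs are invariant to a
global rigid transform of the input landmarks (< 1e-6°, property-tested).

## Preprocessing

1. **Resampling** — both angle streams are cubic-spline resampled onto a
   uniform 300 Hz grid spanning their time range (endpoints preserved
   exactly). A band-limited FIR interpolator would be equally valid; at a
   10–30× oversampling factor of 6 Hz-low-passed signals the difference is
   orders of magnitude below sensor noise.
2. **Synchronization** — the two systems have an unknown clock offset. The
   integer lag is estimated from one channel (default elbow FE, the
   largest-amplitude channel across the four tasks): per-lag Pearson
   correlation of the overlapping segments of zero-phase low-passed copies
   (6 Hz, 2nd order) gives a coarse peak robust to plateaus, amplitude
   distortion and zero padding; exact ties (periodic signals) resolve to
   the smallest |lag|; a Gauss–Newton refinement of the continuous shift
   against a spline of the reference then removes noise-induced peak
   wander, and the result is rounded to an integer. Noise-free shifted
   copies are recovered exactly. The overlap after shifting must be at
   least 1 s; a raw-correlation peak below 0.5 raises a quality warning.
3. **Filtering** — fourth-order zero-lag (forward–backward) Butterworth
   low-pass at 6 Hz, reflective padding of 3×(order+1) samples. Two-pass
   magnitude (1+(f/fc)^8)^-1: DC gain 1, 1 Hz preserved to 0.1%, 20 Hz
   attenuated > 99%, zero phase (all property-tested).
4. **Time normalization** — cubic-spline resampling onto 101 points
   spanning 0–100% of the (pre-segmented) movement, endpoints exact.
5. **Scaling** — a per-channel min–max map to [0, 1] fitted on the pooled
   training inputs *and* targets, so the network's input and output share
   one geometry. Test values outside the training range are not clipped
   (preserves exact invertibility; the network tolerates mild
   extrapolation). The inverse map is exact to 1e-12.

## Refinement network

A stacked 3-layer LSTM, 100 units per layer, maps the 101×4 scaled input
sequence to the 101×4 scaled target sequence; a time-distributed linear
projection (no activation — a minimal regression head) maps the top hidden
state to the 4 channels at every step. Training: mean squared error over
all steps and channels, Adam, learning rate 0.006, batch size 20, whole
sequences as samples, no early stopping and no within-fold validation
split; the incomplete final batch is kept. Weights initialize with the
uniform fan-in scheme U(±1/√H) from the run seed; training and inference
are bit-reproducible given the seed. The implementation is NumPy
(float32, fused gates, exact backpropagation-through-time verified against
finite differences in the test suite).

**Warm-up padding.** The recurrent state starts at zero, which otherwise
leaves a short spurious transient on the first few output samples — enough
to corrupt range-of-motion estimates, since ROM takes a max over the
sequence. Every sequence is therefore prepended with 8 copies of its first
sample during both training and inference, and the corresponding outputs
are discarded. This changes no architectural parameter (an LSTM is
length-agnostic); it only lets the state settle before the first real
sample.

**Cross-validation.** Leave-one-subject-out: one network per held-out
subject per task (per-task models are the default; a pooled-tasks mode
exists but is off by default), with the channel scaler fitted on that
fold's training subjects only. Subject leakage is checked structurally.
Reported statistics are always computed on the held-out subject.

## Agreement statistics

* **CMC** — within-group coefficient of multiple correlation,
  CMC = √(1 − [Σ_gt (Y_gt − Ȳ_t)² / (G(T−1))] / [Σ_gt (Y_gt − Ȳ)² / (GT−1)]).
  The literature contains several variants (within-day, between-protocol);
  this within-group form is adopted as a convention and verified against an
  independent brute-force implementation to 1e-10. Between-system use takes
  G = 2 (one waveform per system per trial), averaged over trials within
  subject, then mean ± SD across subjects. For very dissimilar waveforms
  the radicand goes negative — a known property of the statistic — and the
  value is clamped to 0 and flagged; identical constant waveforms are 0/0
  and return a flagged NaN.
* **RMSE** per channel between aligned 101-point waveforms.
* **ROM** = max − min over the normalized waveform; **PTA** = the final
  (100%) sample — each task's recording ends when the hand reaches its
  target, so the last sample is the target-achievement angle.
* **Bland–Altman** — mean difference ± 1.96 × sample SD (n−1) of the paired
  differences.
* **Paired tests** — Shapiro–Wilk on the paired differences gates a paired
  t-test (normal) vs. the Wilcoxon signed-rank test, α = 0.05, no
  multiple-testing correction. Zero-variance differences are reported as
  degenerate rather than given a p-value.

## Synthetic corpus

No recordings ship with the package; the `synthetic` module generates
paired corpora with the statistical structure the pipeline assumes.

* **Motion.** Each task's channels follow minimum-jerk profiles
  s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ between a start and a subject-specific end
  angle, with an optional mid-movement via-point (reached at 60% of
  movement time) for channels whose range of motion exceeds the
  start-to-end excursion. End-angle means and between-subject SDs are
  anchored to reported gold-standard target-achievement angles of the four
  tasks (e.g. combing hair: shoulder FE 105.89° ± 15.02, elbow FE
  144.56° ± 3.49); start angles are end minus the reported range of
  motion. Movements last 2 s ± 0.2 (a typical reaching duration; not
  reported), preceded by a 1.2 s hold and followed by a 0.6 s hold, at
  300 Hz. All elbow trajectories stay ≥ ~10° flexion, away from the
  extended-arm singularity.
* **Forward kinematics.** The thorax is fixed; the humerus composes
  Rz(FE)Rx(AA)Ry(IE) on the thorax frame and the forearm adds Rz(EFE).
  Markers and skeleton landmarks ride rigidly on their segments, placed so
  that *both* angle models are exact inverses of the generator: zero-error
  streams recover the truth angles to < 1e-6°, so all downstream
  disagreement is attributable to the injected error model. One placement
  is deliberately non-anatomical: the generator's ShoulderLeft landmark
  sits directly anterior of the right shoulder, because the depth-sensor
  trunk construction (z ∝ y × (SR−SL)) can only reproduce the
  marker-model's lateral z-axis if SR−SL is anteroposterior. SL is used
  for nothing else. Angle sign conventions are the generator's own
  self-consistent ones; magnitudes and waveform shapes are what matter.
* **Sensor error.** Applied at the landmark-position level. The dominant
  systematic component mistracks the arm landmarks *within the joint
  planes*: smooth polynomial + sinusoidal functions of the true joint
  angles rotate the whole arm about the lateral axis (flexion-plane
  error), about the anterior axis (ab/adduction-plane error), the wrist
  about the humeral long axis (axial-rotation error, bounded so the
  corrupted elbow stays away from the full-extension fold) and about the
  elbow axis (elbow-flexion error). These bounded rigid mistrackings give
  large, exactly calibratable per-channel errors that can never fold the
  virtual arm through a geometric singularity — an earlier purely
  depth-axis formulation made the axial-rotation channel chaotic
  (180° plane-normal flips) at the error magnitudes the calibration
  anchors require. A secondary set of small depth-axis displacement fields
  on SpineShoulder, SpineMid, ElbowRight and WristRight (with saturation
  caps) preserves the nonlinear propagation of position error through the
  frame constructions. Effective per-channel magnitudes default to the
  plane-dependence ordering IE > FE > AA relative to each channel's range.
  Gaussian jitter (2 mm) and sparse smoothed occlusion spikes add bounded
  noise. A global gain of zero returns the input exactly. The systematic
  error is a deterministic, learnable function of the kinematics — that is
  its contract; it is explicitly a stand-in, not a physical depth-sensor
  model.
* **Calibration.** `calibrate_error_gain` bisects the per-channel gains
  (coordinate-wise, two rounds, since channels still couple through the
  shared alignment step) until the corpus-level uncorrected RMSE matches
  requested anchors — by default the reported uncorrected combing-hair
  magnitudes (shoulder FE 41.73°, AA 11.91°, IE 31.45°, elbow FE 25.83°)
  within 3°. Channels already on target are left untouched, a channel
  whose response to its own gain is non-monotone (field cancellation) is
  accepted if any setting reaches the tolerance, and genuinely
  unreachable targets (e.g. below the jitter floor) raise with the
  achieved value.
* **Corpus.** 13 subjects × 4 tasks × 3 trials by default (subject count
  matches the original cohort; trials-per-task is an assumption). Subjects
  draw body-segment lengths (±5%) and per-task endpoint offsets; trials
  draw endpoint jitter, duration, a uniform 0–1 s inter-system clock
  offset, and fresh sensor noise. Everything is a pure function of the
  master seed.

**What the generator does not emulate:** soft-tissue artifact, marker
occlusion dropouts, true time-of-flight depth physics, trunk motion,
left-arm use, or pathological movement. Passing the synthetic acceptance
suite shows the pipeline is internally consistent and that the network
corrects a large, nonlinear, learnable systematic error under
subject-level held-out evaluation — not that the specific error magnitudes
transfer to any particular real sensor.

## Problem sizes and runtimes

The evaluation runs use 13 subjects, 3 trials per task and 60 training
epochs per fold (the library default is 200 epochs). Sixty epochs is the
package's chosen operating point for the synthetic corpora: training loss
and held-out RMSE are well into their plateau (extending to 100–200 epochs
improves held-out RMSE by ≲ 1°), and a full four-task, 52-fold sweep
completes in roughly a quarter hour on one CPU core. Small toy corpora
(identity or constant-bias recovery in the tests) use more epochs
(300–600) because with 20 sequences one epoch is a single optimizer step.

## Known limitations

* The network is unidirectional; even with warm-up padding the first
  samples carry less context than later ones.
* With only a dozen training sequences per fold the MSE objective barely
  distinguishes "track the input" from "reproduce the typical training
  waveform", so on noise-free (identity) corpora the held-out error of
  subjects with extreme movement amplitudes plateaus near 2–3° on the
  flexion channels however long training runs. A residual (skip)
  connection would remove this but is deliberately not used: the model is
  a direct sequence map with a linear head, not a residual corrector. On
  realistic corpora with injected sensor error the effect is dominated by
  the error being corrected.
* CMC variant choice is a convention (see above); absolute CMC values are
  not comparable across variants.
* The synchronization quality threshold (raw Pearson 0.5) is heuristic;
  heavily corrupted streams can align with systematic offsets of up to a
  few tens of milliseconds, which the refinement network then absorbs as
  part of the learnable error.
* Gimbal-lock handling zeroes IE by convention; waveforms passing within
  1° of |AA| = 90° will show a convention-dependent FE/IE split.
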