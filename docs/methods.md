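# Methods

`spineimu` implements the measurement chain of a two-IMU telerehabilitation
system for spine exercises: per-sensor attitude estimation, IMU-to-segment
calibration, joint-angle extraction, and a window-feature classifier that
identifies which body site each IMU is strapped to. This note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Attitude estimation

Each 9-axis IMU (accelerometer, gyroscope, magnetometer, 100 Hz) is fused
with a direct complementary filter — a nonlinear observer on SO(3). Let
`q` be the estimated body-to-global unit quaternion. Per frame the
innovation is the sum of cross products between measured and predicted
reference directions in the body frame:

    e = a/|a| × (Rᵀ ĝ)  +  Rᵀ [ (m_g/|m_g|) × m̂_h ]_z-only

where `a` is the accelerometer sample, `ĝ` the global gravity direction,
`m_g` the magnetometer sample rotated into the global frame and projected to
the horizontal plane, and `m̂_h` the horizontal reference field. The
corrected rate `ω + kp·e + ki·∫e` drives a first-order quaternion
integrator at dt = 1/rate, followed by renormalization.

Parameters (all exposed in `FilterParams`):

| parameter | default | units | role |
|---|---|---|---|
| `kp` | 1.0 | 1/s | proportional pull toward vector observations (~1 s correction constant, well damped) |
| `ki` | 0.1 | 1/s² | integral term absorbing residual constant gyro bias |
| `acc_gate_g` | 0.3 | fraction of g | gravity correction skipped when \|‖a‖ − g\| exceeds this, rejecting high-dynamic frames |
| `g_ref` | (0, 0, 9.81) | m/s² | global gravity (z up) |
| `m_ref` | (0.643, 0, −0.766) | unit | magnetic field with a mid-latitude ~50° downward dip |

Two deliberate asymmetries: the accelerometer is used only as a gravity
*direction* (normalized), and the magnetometer corrects only heading (its
error vector is projected onto the vertical axis before being mapped back to
the body frame), so magnetic dip and indoor field distortions cannot corrupt
tilt. Magnetometer use defaults to on; supine/quadruped poses near steel
structures may warrant `use_magnetometer=False`, at the cost of unobservable
heading drift equal to the residual z-gyro bias.

The filter is warm-started by a TRIAD fix computed from the first ~0.1 s of
accelerometer/magnetometer data (`initial_orientation`). Without it, the
observer spends the static calibration window converging from identity and
the alignment estimate inherits that transient; a warm start is what a
deployed filter would do anyway, since the sensors stream before the trial
begins. First-order (Euler) integration at 100 Hz keeps the per-frame cost
at what a real-time mobile implementation can afford; its error at the
rates these exercises reach (≲ 90°/s) is ~2·10⁻⁵ relative, far below the
sensor error budget.

## Calibration, joint angles, metrics

Gyro bias is the per-axis mean over a 10-s stationary table capture (or,
absent one, over the trial's own 3-s static lead); a warning fires if the
window's residual RMS exceeds 0.02 rad/s.

IMU-to-segment alignment uses the 3-s static initial pose: each sensor's
alignment quaternion is the conjugate of its mean orientation over the
window (chordal mean via the dominant eigenvector of Σqqᵀ, which is
invariant to per-sample sign flips). This is the minimal construction that
makes both segment orientations — and hence the joint quaternion
`q_joint = q_prox* ⊗ q_dist` — identity at calibration, so the initial pose
is the zero-point of every reported angle.

Angles come from the ZXY Euler decomposition of the joint rotation matrix,
`R = Ry(α)·Rx(β)·Rz(γ)`:

    α = atan2(R₁₃, R₃₃)   (y-axis yaw → "rotation")
    β = asin(−R₂₃)        (x-axis pitch → "abduction")
    γ = atan2(R₂₁, R₂₂)   (z-axis roll → "flexion")

Two-argument arctangents recover the full (−180°, 180°] range — a
single-argument arctan would fold any exercise crossing ±90°. α and γ are
additionally unwrapped across frames (180° jump threshold), so a continuous
350° sweep reads as 350°, not −10°. Frames within 1e-9 of the |β| = 90°
singularity are flagged (`gimbal_frames`) rather than raised when processing
a track, since a transient crossing should not abort a trial; the scalar
`euler_zxy` raises `GimbalLockError` carrying the degenerate β.

Agreement metrics between an estimated and reference track: MAE (mean
absolute difference, degrees); peak error — repetitions are segmented on the
reference with a hysteresis threshold at 50% of its range, and per
repetition the *signed* difference of maxima is averaged, so systematic
over/undershoot keeps its sign (the near-zero-mean, large-spread statistic a
signed definition produces); mean velocity error — mean absolute difference
of central-difference angular velocities, deg/s. Repetition counting uses
the same hysteresis state machine (rearm below threshold−10% of range); a
flat track counts zero.

## Placement identification

Identification happens at the start of a trial, so only the first 10 s of
each recording are used. Windows of 300 samples (3 s) slide with a 1-sample
stride — 701 windows per 10-s trial. Per window, each of the 6 inertial
channels (3-axis acc + 3-axis gyro) yields 14 features: mean, std, RMS,
median, skewness, kurtosis, waveform length, zero crossings, slope sign
changes, mean absolute value, IQR, MAD, spectral peak frequency and spectral
peak index — 84 features per IMU window, channel-major order, serialized
with stable names.

Degenerate-case conventions (fixed so synthetic inputs are deterministic):
population moments; skew/kurtosis (excess) defined as 0 when the window
variance is 0; zero crossings count strict sign changes of the mean-removed
signal with zeros inheriting the previous sign; slope sign changes apply the
same rule to the first difference with no amplitude deadband; spectral
features use the one-sided FFT magnitude of the raw (untapered) window with
the DC bin excluded — peak frequency is the argmax bin in Hz, peak index its
integer bin.

Features are z-scored (population σ, floored at 1e-12) with the scaler
fitted on training rows only. Channel pruning trains an XGBoost classifier
(200 trees, depth 4, learning rate 0.1, subsample 1.0, `hist`,
single-threaded — fixed for reproducibility, overridable) on the *entire*
dataset, ranks channels by normalized gain importance (ties broken by stable
feature order), and keeps the shortest prefix reaching 90% cumulative
importance. Ranking on the full dataset mirrors the deployed procedure but
leaks label information across subject splits; evaluation reports carry a
`leakage_flag`, and passing a train-only subset with
`ranked_on_full_data=False` gives the strict variant.

The classifier is LDA on the selected, standardized features. When the
pooled within-class scatter is singular (likely with 84 correlated features
over short windows) the fit falls back to the lsqr solver with Ledoit-Wolf
shrinkage, with a warning. The deployable export is exactly
`p = softmax(W·(x−μ)/σ + b), y = argmax p` — W, b, μ, σ, class labels and
feature-name order in one JSON, which reloads bit-faithfully (floats
round-trip via shortest-repr JSON serialization) and reproduces the
in-memory model's posteriors to better than 1e-10.

Evaluation is subject-wise: 9 training / 3 test subjects per split, 10
random splits, scaler and LDA refitted per split on training subjects only;
accuracy is the fraction of correctly classified windows and the confusion
matrix (row-normalized by true class) is averaged over splits. Argmax ties
go to the lowest class index. Site labels are coded 1–5 in the fixed order
head, thorax, pelvis, upper_arm, thigh.

## Synthetic data

No public recordings of this protocol exist, so every claim is validated on
a rigid-body simulator whose *inversion* is the pipeline under test.

**Trials.** Two segments share a joint; the proximal segment holds a fixed
non-trivial orientation, the distal rotates about the global axis of the
exercise channel (flexion → z, rotation → y, abduction → x) through a
raised-cosine profile θ(t) = A/2·(1 − cos 2πt/T) — five repetitions of
T = 3 s after a 3-s static lead. Default amplitudes are 40° (flexion,
abduction) and 60° (rotation) — placeholder ranges of motion, since real
per-exercise ROMs are subject-specific. Both IMUs carry fixed non-identity
mountings so the calibration step is genuinely exercised. Sensor models:
gyro = body rate + constant bias + white noise; accelerometer = body-frame
gravity + lever-arm linear acceleration (ω̇×r + ω×(ω×r), 0.1 m arm);
magnetometer = body-frame field + noise. Default noise — gyro σ 0.005 rad/s,
bias 0.01 rad/s per axis, acc σ 0.05 m/s², mag σ 0.5 µT — is
consumer-MEMS order of magnitude. Frames drop i.i.d. (0.42% at the nominal
3-m Bluetooth range), survivors keep their package numbers so the repair
stage sees realistic gaps; the first and last frames always survive so
stream extents are well-defined.

**Placement corpus.** Per subject × exercise × site, a 10-s stream whose
signature is a site-specific static orientation (five distinct gravity axes
in the sensor frame) plus a site-specific oscillation (amplitude 10–30°,
frequency 0.6–1.5 Hz) about a body-fixed axis after a 3-s static lead.
Subjects contribute consistent jitter (≈5°/axis orientation, 10–15%
amplitude/frequency, per-subject gyro bias), exercises modulate frequency,
and sensor noise is added throughout.

**What passing does and does not show.** The simulator is rigid-body exact:
no soft-tissue artifact, no alignment drift during a trial, no magnetic
disturbance fields, no multi-joint coupling, and site signatures far cleaner
than human between-site differences. Noise-free inverse consistency
(MAE < 0.5° across all ten exercises) therefore validates the *algebraic
correctness* of the chain, and the noisy-condition MAE (< 3°, the order of
errors reported for comparable hardware) the *noise robustness* of the
observer — neither is a claim about accuracy on human data. Likewise the
placement corpus is linearly separable by construction; its near-perfect
accuracy validates the pipeline mechanics (windowing, scaling, pruning,
subject-wise evaluation, export), while the random-subset comparison checks
that importance pruning finds the informative channels, not that 92.97% is
reproduced.

## Numerical choices

Quaternions are scalar-first, Hamilton convention, canonicalized to w ≥ 0 on
output (q and −q are one rotation; the canonical sign makes tests
deterministic). Unit norm is enforced to 1e-9 after normalization and
checked to 1e-6 before matrix conversion. Gimbal-lock band: |R₂₃| ≥ 1−1e-9
(double-precision arcsin domain safety). Stream repair refuses gaps longer
than 100 frames (1 s) — dropouts that long invalidate fusion. Problem sizes
in the test and acceptance runs: 18-s trials at 100 Hz for angle estimation;
the placement corpus at window stride 50 (the 1-sample deployment stride is
exercised on single streams, and the 701/420,600 window counts are verified
arithmetically over the generated corpus).
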