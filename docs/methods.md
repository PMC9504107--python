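# Methods

## Conventions

All rotations are unit quaternions in Hamilton convention (right-handed,
``ijk = −1``), scalar-first ``(q0, q1, q2, q3)``, canonicalized to
``q0 ≥ 0`` (q and −q encode the same rotation). Euler angles use the
aerospace ZYX sequence: ``R = Rz(yaw) · Ry(pitch) · Rx(roll)`` maps
sensor/body vectors into the global frame.

Three frames are used. The **global frame** is north-east-down: x north,
y east, z toward the ground. The **sensor frame** is each node's own axes;
the **body frame** of a segment coincides with the global frame when the
wearer stands in the north-facing neutral stance. The accelerometer is
modelled as reading the gravity *direction* ``(0, 0, 1)`` g when static
(the sign convention under which roll = atan2(a_y, a_z) gives zero for a
level node); the simulator uses the same convention, so implementation and
synthesis are consistent by construction. The default earth field is
``(0.25, 0, 0.4)`` gauss — a mid-latitude field with a downward dip —
configurable everywhere a field appears.

## Magnetometer calibration

Hard iron adds a constant offset to magnetometer readings and per-axis scale
errors stretch the locus of a field sweep from a sphere into an axis-aligned
ellipsoid. The model deliberately carries **no cross terms** — soft iron is
approximated as axis-aligned scaling — so the fit is linear: solve
``p₁x² + p₂y² + p₃z² + p₄x + p₅y + p₆z = 1`` by least squares, read the
center from ``−p₍₃₊ᵢ₎/2pᵢ`` and the semiaxes from the recentred constant.
Only the products (semiaxis · field modulus) are identifiable, so the
reported R is the geometric mean of the semiaxes; for a spherical locus
a = b = c = R exactly. Calibration maps a raw reading component-wise to
``(raw − offset) · R / semiaxis``.

Degenerate coverage (a planar wand wave) is detected from the eigenvalues of
the centered scatter matrix and rejected rather than silently extrapolated;
at least 9 samples are required. A fit on noiseless synthetic data is exact
to machine precision; with 2% radial noise the offsets are recovered within
a fraction of a percent of R (seeded tests assert the 5% bound).

## Inertial bias estimation

The wearer stands still for at least 1 s at the start of a recording. Over
that interval the mean gyro reading is the bias; the accelerometer bias is
the mean reading minus the unit vector along its direction (direction is
attitude, magnitude error is bias). Only biases are subtracted — white noise
is left for the orientation filter, which averages it out by design.

## Orientation fusion

The static attitude comes from the closed forms

    roll  = atan2(a_y, a_z)
    pitch = asin(−a_x / |a|)          (argument clipped to [−1, 1])
    h_Gx  = h_x cosθ + h_y sinθ sinφ + h_z sinθ cosφ
    h_Gy  = h_y cosφ − h_z sinφ
    yaw   = −atan2(h_Gy, h_Gx)

with a 20% accelerometer-norm gate (`NotStatic` otherwise). The third term
of ``h_Gx`` uses the standard ``sinθ cosφ`` tilt compensation; the
``sinθ sinφ`` variant sometimes seen in print breaks the level closed-form
cases and is not used.

During motion the filter is the complete gradient-descent MARG update: per
frame, ``q̇ = ½ q ⊗ (0, ω) − β ∇f/‖∇f‖`` integrated at dt = 1/rate and
renormalized. The objective stacks two residuals
``f(q, n_G, n_S) = vec(q* ⊗ (0, n_G) ⊗ q) − n_S`` — gravity
(``n_G = (0,0,1)`` vs. the normalized accelerometer) and the magnetic field
(``n_G = (b_x, 0, b_z)``, the measured field rotated to global by the
current estimate and flattened onto the x–z plane, so the magnetometer can
only pull on yaw). The gradient is the analytic ``Jᵀf``; tests verify it
against finite differences. β defaults to 0.1: at 400 Hz this suppresses a
0.5 deg/s gyro bias to well under 2° of terminal yaw error over 60 s, where
open-loop integration (β = 0) drifts 30°.

A bare normalized-gradient iteration (``q ← q − ξ∇f/‖∇f‖``, ξ = 0.1
default) is exposed as `gradient_step` for static use. Because the step has
fixed size, it orbits the optimum at a distance of order ξ rather than
converging; `solve_static` wraps it with a halve-on-non-improvement step
schedule and reaches fractions of a millidegree in tens of iterations.

The sensor→body mount offset is captured during the neutral stance, where
body ≡ global, as the sign-aligned renormalized mean of the per-frame
sensor→global estimates over the still window (adequate for tightly
clustered rotations; no eigen-decomposition averaging is needed). Thereafter
``q_BG(t) = q_SG(t) ⊗ q_SB*``.

## Skeleton model

Fifteen segments form a tree rooted at the pelvis: pelvis – waist – chest –
neck – head up the trunk, shoulder/upper-arm/forearm chains per side, and
thigh/calf chains per side. Neutral-pose directions are trunk and head up,
shoulders mediolateral, arms and legs down; default lengths are standard
anthropometric fractions of stature (default 1.70 m), overridable per
segment. Ten worn nodes drive the tree; the neck, head, shoulders inherit
the chest orientation and the waist inherits the pelvis, so both the
ten-node and a denser placement are supported by the same assignment map.

Forward kinematics runs depth-first: ``D₁ = D₀ + q ⊗ (0, l·û) ⊗ q*`` with
the child's start bound to the parent's end, which makes connectivity and
segment-length conservation exact by construction (asserted to 1e-9 in
tests). The pelvis root stays at the origin — the recorded tasks are seated,
so root translation carries no information here.

Joint angles are ``arccos`` of the clamped normalized dot product of the two
segment vectors, in degrees within [0°, 180°]: elbow EF (upper arm vs.
forearm), knee KF (thigh vs. calf), shoulder SF (chest vs. upper arm,
i.e. trunk-referenced), breast BF (chest vs. waist), and waist WF (waist
vs. the mean of the two thigh vectors — the output schema has a single WF
column, and averaging the thighs keeps it symmetric). Under this raw
adjacent-segment convention a straight standing pose reads EF = KF = 0° and
WF = 180°, and an upright sitting pose reads KF = WF = 90°.

## Feature extraction and classification

Windows are 1000 ms with 50% overlap (stride = half window, trailing partial
dropped): ``floor((N − w)/(w/2)) + 1`` windows. Per window and channel, 23
features:

* 12 time-domain — mean, median, std, median absolute deviation, 25th/75th
  percentiles, IQR, skewness, excess kurtosis, variance, Shannon entropy of
  a 16-bin amplitude histogram (natural log), spectral entropy of the
  normalized one-sided power spectrum (DC excluded: offsets carry no motion
  content).
* 6 frequency/AR — frequency, value, and total-power share of the spectral
  maximum; main-peak value plus second-peak height and frequency of an
  order-4 Yule-Walker autoregressive spectrum evaluated on a 256-point grid
  to Nyquist (autocovariances with the (n−k) "adjusted" denominator).
* 5 band powers — equal-width bands covering 0–10 Hz, the band where seated
  body motion lives.

Constant windows return skewness = kurtosis = 0 and both entropies 0, and
the AR block returns zeros, so no feature is ever NaN. The whole extractor
is cross-checked to 1e-9 against an independently coded implementation
(scipy.stats / statsmodels) in the tests and the acceptance script.

Evaluation carves a stratified 20% test split first, selects the best
candidate per classifier family by mean 10-fold cross-validated accuracy on
the remainder (small hyperparameter grids: C for logistic regression and
SVM, depth for the tree, k for KNN, 100 trees for the forest), refits on the
full training portion, and reports test accuracy, weighted
precision/recall/F1, and micro-averaged one-vs-rest ROC-AUC and AUPRC.
Features are standardized inside each pipeline so no leakage crosses the
splits; everything is deterministic for a fixed seed.

## Synthetic data

The simulator is the package's ground-truth source. `MotionScript`
prescribes per-segment body→global trajectories as fixed-axis sinusoids,
PCHIP-interpolated keyframes, their composition (`ComposedMotion`, e.g. a
yaw sweep times a pitch rock for a full-coverage calibration wave), with an
optional smoothstep ramp so motion can start from the neutral stance without
a pose discontinuity. A continuity guard rejects scripts whose inter-frame
rotation exceeds 10°.

`synthesize_trace` inverts the measurement models: gyro from the exact
backward quaternion increments (so integration of the synthesized rates
reproduces the script), accelerometer as the sensor-frame gravity direction,
magnetometer as the sensor-frame field pushed through the *inverse*
calibration map. Injected corruption covers gyro bias + white noise, accel
white noise, and magnetometer hard-iron offset, axis scales and noise, with
defaults on the scale of a consumer MARG node (0.04 deg/s gyro noise,
0.005 g accel noise, tenths-of-gauss hard iron). All randomness flows from
one seed; identical seeds give bit-identical traces.

The four-task dataset generator emits labeled joint-angle series directly
(1 = recite, 2 = reading comprehension, 3 = browse, 4 = music) from per-task
recipes: distinct mean postures and sway waveforms — e.g. fast small
bilateral elbow oscillation for reciting, a right-arm writing motion with a
forward lean for reading comprehension, near-stillness for browsing, and a
large slow trunk sway for music — with within-class Gaussian jitter (2° on
means, 10% on amplitudes, 5% on frequencies) plus 0.5° measurement noise.
These recipes are separable by construction, which is the point: they make
the *pipeline* testable (windowing, features, evaluation protocol), not the
difficulty of the recognition problem. Passing classification tests
therefore demonstrate correctness of the machinery, not expected field
accuracy on real workers, where inter-subject variability, soft-tissue
artifact and overlapping behaviours will lower all scores.

**What the simulator does not model:** linear (non-gravitational)
acceleration — the seated tasks are quasi-static and the static-attitude
formulas assume it; soft-tissue artifact; magnetometer soft-iron
cross-coupling beyond axis scaling (mirroring the calibration model class);
magnetic disturbance transients.

## Resampling

Streams recorded at different rates (e.g. a 120 Hz optical reference next to
400 Hz nodes) are aligned by piecewise-cubic Hermite interpolation. Node
derivatives come from the local cubic through each point's four nearest
nodes, which makes the interpolant **exact on cubic polynomials**; a
`monotone=True` variant switches to PCHIP slope limiting, which cannot
overshoot monotone data but gives up cubic exactness — the two goals are
mutually exclusive, so both are offered and the default favours accuracy.

## Numerical choices

* Quaternion geodesic distances use the chord form ``‖Δq‖ = 2 sin(θ/4)``,
  which keeps full precision for tiny angles where ``acos`` of the dot
  product floors out near 1e-8.
* ``asin``/``acos`` arguments are clipped to [−1, 1] throughout to survive
  noise.
* At gimbal lock (|pitch| = 90°) the Euler decomposition pins roll = 0.
* The fusion gradient step is skipped when ``‖∇f‖ < 1e-12`` (converged).
* Constant windows short-circuit the spectral features (FFT round-off in
  the non-DC bins would otherwise fabricate spectral entropy).

## Problem sizes

The test suite and acceptance script size their simulations for a desk-scale
run: 10 s at 400 Hz for the orientation round trip, 60 s at 400 Hz for drift
suppression, 800 points for calibration recovery, a 6 s ten-node capture at
200 Hz for the end-to-end knee-flexion check, and 100 windows per class for
classification. These sizes are the package's chosen defaults; every
property they verify is rate- and duration-stable by construction.

## Known limitations

* The axis-aligned ellipsoid cannot correct rotated soft-iron distortion; a
  full 9-parameter quadric is out of scope by design.
* The normalized gradient correction has fixed magnitude β, so under sensor
  noise the static error of the fused filter grows mildly with β once drift
  is suppressed; β = 0.1 is a robust default for 400 Hz, not an optimum.
* Joint angles are unsigned (flexion magnitude only); hyperextension is
  indistinguishable from flexion at the same magnitude.
* The pelvis root does not translate; gait or locomotion tasks would need a
  root-trajectory model.
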