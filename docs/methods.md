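# Methods

This note documents the models, algorithms and numerical choices behind
`gaitagree`, in the order data flows through the pipeline, followed by
the design of the synthetic gait generator and what validation against it
does and does not establish.

## Coordinate conventions

All kinematics live in a canonical body-axes frame: X = subject's right,
Y = up, Z = anterior (the walking direction). A depth camera placed in
front of a treadmill reports X-right / Y-down / Z-away-from-lens; since
the camera faces the subject, the reader maps that frame with Y and Z
negated (`DEPTH_CAMERA_AXES`). Axis maps are signed permutations, hence
isometries: canonicalization never distorts inter-joint geometry.

Streams are *not* assumed sample-synchronized across devices. Each
stream carries its own timestamps on a shared wall clock (simultaneous
recording start, with a configurable per-stream offset); only the
analysis window aligns them. This mirrors comparing the same time
interval rather than individual steps between systems.

## Preprocessing

* **Filters.** IMU channels: 4th-order Butterworth low-pass at 10 Hz.
  Skeleton joint trajectories: 1st-order at 6 Hz. Both default to
  zero-phase (forward–backward) application, with the stated order as the
  per-pass design order. Zero lag matters here because event *times* from
  the two modalities are compared; a causal filter would shift camera
  events by tens of milliseconds relative to IMU events. Single-pass
  filtering remains available per config.
* **Trimming.** The walking segment is the longest run with belt speed
  above 0.2 m/s sustained for at least 2 s. The threshold is far below
  any plausible preferred walking speed; the debounce rejects isolated
  logging spikes.
* **Window.** The last 120 s of the walking segment. Shorter segments
  are clipped with a warning and the achieved length is recorded, so
  downstream averages always state their support.

## Gait-event detection

**Camera (position-based).** Per side, r(t) = Z_ankle − Z_pelvis.
Maxima of r (foot most anterior relative to the pelvis) are initial
contacts, minima are toe-offs. Peaks are found in two passes: a rough
prominence pass estimates the median stride period, then a constrained
pass enforces a minimum spacing of 0.5 × median stride. Peak times are
refined to sub-frame precision by parabolic interpolation of the three
samples around each extremum. IC/TO alternation is enforced by dropping
the lesser-prominence member of any same-kind consecutive pair.

The ankle (not heel or toe) drives the detector: stride length is also
defined at the ankle, and the heel is among the less reliably tracked
landmarks; the landmark is configurable. The pelvis joint is the body
reference (the classic sacrum marker has no direct equivalent in the
depth-camera joint set).

An extremum-based detector necessarily places events slightly *inside*
the contact phase: the ankle's anterior maximum occurs where its
camera-frame velocity crosses zero, which precedes the instant the foot
is fully belt-locked. On the simulator this offset is ≈ 22 ms — under
one camera frame, so IC-based parameters are unaffected (the offset
cancels in IC-to-IC differences) — but it biases camera support times
(see Limitations).

**Foot IMU (gyro-based).** The mediolateral angular velocity shows one
dominant positive peak per swing. Swing peaks are found with a
height/prominence floor of 0.3 × the median swing-peak height and the
same 0.5-stride spacing rule; IC is the first local minimum after each
swing peak and TO the last local minimum before it. Minima must have
prominence ≥ 0.1 × the median swing-peak height — without that floor,
millinumeric ripple introduced by the zero-phase filter produces spurious
"first" minima. The rough pass thresholds on 0.5 × the maximum positive
value (not the signal span), because the negative contact dips can be
deeper than the swing peak itself.

## Parameters

* **Stride time** — ipsilateral IC-to-IC.
* **Stride length, camera** — ΔZ_ankle between consecutive ICs plus the
  belt translation ∫v_belt dt over the stride (trapezoidal, with
  interpolated interval endpoints). On a treadmill the ankle's
  camera-frame displacement is near zero; the belt term carries the
  distance.
* **Stride length, IMU** — v(t) = −v_belt(TO) + ∫a_AP dt over
  [TO, IC]; d = ∫v dt; length = d + belt translation over [TO, IC].
  The initial condition encodes that the foot rides the belt until
  toe-off. This is the unique reading of "double integration plus
  treadmill translation" under which the formula equals the belt-relative
  stride length for periodic gait (length = v_belt × T when the belt term
  covers [TO, IC]; the full-stride alternative is available behind a
  config switch and double-counts the stance translation).
  Optional linear dedrifting (default on) corrects the velocity so
  v(IC) = −v_belt(IC) — a zero-velocity-update analogue that absorbs
  additive accelerometer bias (a 0.05 m/s² bias leaves ≤ 2 cm error with
  dedrifting; without, the error grows with the square of swing
  duration).

  The acceleration is integrated **as recorded**, not low-passed: the
  10 Hz filter exists for event detection, and smearing the landing
  transient across the integration boundary biases the displacement by
  several centimetres (verified numerically), while the integral itself
  already suppresses high-frequency noise. Real-device use assumes a
  gravity-free, world-aligned anteroposterior channel (orientation fusion
  for free-moving sensors is out of scope; the simulator's `REALISTIC`
  sensor mode exists to test gravity/orientation handling with a known
  pitch profile).
* **Support times** — per stride of side S: single support = the
  contralateral swing (contralateral TO → IC inside the stride); double
  support = the sum of the two bilateral-contact intervals. For
  symmetric gait with duty factor d these equal (1−d)·T and (2d−1)·T.
  Strides missing the needed events carry NaN, never zero.
* **Cadence** — bilateral IC count per minute over the window (steps,
  not strides; the operational definition is stated here because
  reporting conventions vary).
* **Step width** — |X_ankle,L − X_ankle,R| at each initial contact,
  averaged per stride. Note this is an ankle-centre width, systematically
  wider than widths defined at the inner foot boundaries.
* **Margin of stability** — XCoM = CoM + v_CoM/ω₀ per axis, with CoM the
  pelvis midpoint, v_CoM by central differences on the 6-Hz-filtered
  pelvis track (forward/backward differences at window edges), and
  ω₀ = √(g/ℓ), g = 9.81 m/s². ℓ defaults to the participant's leg
  length; the fallback is the mean ankle-to-pelvis distance at ICs.
  ML margin: leading ankle X minus XCoM X, signed positive when the XCoM
  is medial of the leading ankle (stable, the usual extrapolated-CoM
  convention). AP margin: leading toe Z minus XCoM Z; NaN when the toe
  landmark is missing (the ML margin then still computes from the ankle).
  With zero CoM velocity the margin reduces exactly to the geometric
  CoM-to-BoS distance.
* **Arm swing, IMU** — integrate the wrist angular velocity about its
  dominant rotation axis (first principal axis of the windowed gyro
  covariance), dedrift linearly per cycle, and take the peak-to-peak
  angle per swing cycle (cycles delimited by successive positive-going
  zero crossings of ω).
* **Arm swing, camera** — arm length r = median wrist–shoulder distance
  in the window; for each successive pair of extreme wrist positions the
  chord c gives the swing angle arccos((2r² − c²)/2r²). Chords beyond
  the 2r diameter (noise) clamp to 180° and are counted. Isotropic
  wrist-position noise *inflates* this estimate (the expected noisy chord
  exceeds the true chord, and extremum selection picks the most extreme
  noisy sample); the test suite quantifies the bias against a Monte-Carlo
  oracle rather than pretending it away.
* **Window summary** — arithmetic mean of each parameter over all strides
  (sides pooled; sided parameters like arm swing additionally averaged
  within side), with stride counts and achieved window length recorded.

## Agreement statistics

One row per parameter across participants, difference direction fixed as
IMU − camera: Shapiro–Wilk normality per method; two-sided paired t-test
(degenerate zero-variance differences are reported as an exact-offset
flag rather than a fabricated t); Pearson correlation when both margins
pass normality at α = 0.05, Spearman otherwise, with the choice recorded;
Bland–Altman mean difference, sample SD (n−1), limits of agreement
mean ± 1.96·SD, and the count strictly outside the limits. No
multiple-testing correction is applied (single α = 0.05 by design).
The 1.96 multiplier (not 2.0) is the default because the standard
limits-of-agreement definition uses the normal 95% quantile; it is a
config knob. Participants missing a modality are dropped per parameter
with a logged count.

## The synthetic gait generator

The generator produces the three device streams for a steady-state
treadmill walker with exact ground truth. Trial structure: 3 s quiet
standing, 3 s belt ramp, `duration_walk` of steady walking, 3 s ramp
down, 3 s standing — so trimming and window selection face realistic
bookends.

Kinematic model, per foot:

* **Stance**: the foot rides the belt; camera-frame velocity equals
  −v_belt(t) exactly, including during ramps.
* **Swing**: the anteroposterior velocity is −v₀ plus two narrow
  Gaussian-CDF transition layers (σ = 5 ms, centred 4σ inside each end)
  and a smooth polynomial bump whose height is solved per stride so the
  foot lands exactly at its fixed per-foot anterior position. The foot
  therefore leaves the belt *at* −v_belt and returns to −v_belt just
  before contact. Two consequences drove this specific shape:
  1. the anterior-position maximum falls ≈ 22 ms before true IC — within
     one camera frame, so the position-based detector meets its accuracy
     contract while still exhibiting the real method's small inward bias;
  2. Gaussian layers are spectrally compact, so trapezoidal integration
     of the 128 Hz-sampled analytic acceleration reproduces the swing
     displacement to a few millimetres — polynomial-smoothstep layers
     sharp enough for (1) alias badly at 128 Hz and break double
     integration by centimetres.
  Landing at a fixed anterior position is the stiff limit of a
  mean-reverting landing rule: the walker never drifts off the belt, and
  the true stride length is *exactly* the belt translation per stride
  (the conservation identity the camera estimator is built on).
  Vertical clearance is a sin² bump (default 5 cm).
* **Stride timing**: cycle periods are T·(1 + cv·η), η ~ N(0,1), floored
  at T/2 and logged in the ground truth; the left–right phase offset
  defaults to half a stride.
* **Foot pitch gyro**: a positive mid-swing Gaussian lobe (peak 4 rad/s,
  σ = swing/8) minus two narrow dips (σ = 20 ms) centred exactly at TO
  and IC, with areas balanced so the pitch angle returns to zero each
  stride; the pitch angle is the closed-form erf integral. This is the
  signature the gyro-based detector keys on, with the dips at the true
  event times by construction.
* **Pelvis (CoM)**: mediolateral sway at stride frequency (default
  2 cm amplitude, phased to peak over the stance foot), vertical bounce
  at twice stride frequency (1.5 cm); the noise-free pelvis path is the
  ground-truth CoM trajectory.
* **Arms**: wrists rotate about fixed shoulder points in the sagittal
  plane, anti-phase to the ipsilateral leg, angle (A/2)·sin(2πu + φ);
  the wrist gyro is the analytic angle rate and the wrist accelerometer
  the analytic second derivative of position.
* **Amplitude envelope**: all oscillatory amplitudes ramp in/out over two
  strides at the walking-phase boundaries so the standing bookends are
  genuinely still. (Envelope derivatives are neglected in the analytic
  accelerations; the affected strides sit at the walk boundaries, outside
  any analysis window.)

IMU channels are analytic derivatives throughout — nothing is numerically
differentiated. `IDEALIZED` sensor mode emits world-aligned gravity-free
channels (the exact-oracle convention); `REALISTIC` rotates into a
pitched sensor frame and adds gravity.

Default profile (belt 1.05 m/s, T = 1.1 s, duty 0.60, step width 0.12 m,
ML sway 2 cm, arm swing 30°, leg length 0.90 m; noise off unless set)
sits inside ranges typical of older adults at preferred treadmill speed.
These are configuration, not claims about any population. Realistic
noise, where the suite uses it, means 3 mm per-joint skeleton noise
(25 mm at the wrists, reflecting the much poorer wrist tracking of
pose-estimation systems), 0.05 m/s² accelerometer and 0.01 rad/s gyro
noise, and stride-time CV 0.02.

**What the generator does not emulate**: pose-estimation artifacts
(body-part swaps, occlusion dropouts, depth-dependent bias), soft-tissue
and mounting artifacts on IMUs, gait asymmetry and pathology,
turning/overground bouts, foot rollover geometry (ankle and toe follow a
simplified rigid-foot pitch), and any dynamics (it is a kinematic
harness, not a claim about older-adult gait). Passing the suite
demonstrates that the *estimators implement their definitions correctly
and are robust at realistic noise amplitudes* — not that a real camera
achieves these accuracies on real patients.

## Numerical choices and degenerate inputs

* Trapezoidal integration everywhere a signal is integrated (belt
  translation, velocity, displacement, gyro angle), with exact interval
  endpoints interpolated for the belt term.
* Parabolic sub-sample refinement of every detected peak/minimum.
* Zero-variance paired differences: exact-offset flag, not a t statistic.
* Chords beyond the law-of-cosines domain clamp to 180° and are counted.
* Missing joints/events yield absent values (NaN), never zeros; tables
  keep modality-specific columns only where computable.
* Skeleton tracking dropouts: linear interpolation up to 3 frames
  (~100 ms); frames inside longer gaps are dropped with a logged count.
* Readers refuse files that would silently change units (IMU files must
  declare accel/gyro units; unknown strings are format errors).

## Known limitations

* Camera-derived single/double support times inherit the extremum
  detector's inward event bias (tens of milliseconds at 30 Hz) and should
  not be used for fine comparisons — consistent with the general finding
  that camera support times are the least reliable of these parameters.
  The suite asserts this bias rather than hiding it.
* The AP margin of stability depends strongly on where the anterior BoS
  bound is taken and on the camera-frame CoM velocity convention; values
  are comparable within a pipeline, not across conventions.
* The IMU stride-length estimator assumes a gravity-free, world-aligned
  AP channel; free orientation estimation is out of scope.
* Agreement statistics assume one trial per participant (no
  repeated-measures limits of agreement or proportional-bias regression).
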