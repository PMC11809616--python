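# Methods

## Sensing model

A chest-worn smartphone accelerometer at quasi-static trunk speeds measures
specific force dominated by gravity. In the device frame (portrait on the
sternum: +y cranial, +x toward the wearer's right, +z anterior), the upright
reading is ≈ (0, +g₀, 0) with g₀ = 9.80665 m/s². Samples whose magnitude
falls outside [0.5 g₀, 3 g₀] (free fall, impacts, shaking) are flagged
invalid; they are never dropped, but they do not update the gravity
estimate.

Gravity is estimated with a per-axis exponential moving average,
`gₖ = α aₖ + (1−α) gₖ₋₁`, seeded with the first valid sample. The default
α = 0.2 per sample at 50 Hz gives an effective time constant of ~0.1 s —
enough to suppress sensor noise and hand tremor while keeping lag small
relative to the multi-second postural events being detected. The EMA was
chosen over zero-phase or FIR filtering because monitoring is causal and
must run on low-end hardware; α is configurable and any input rate is
accepted.

## Deviation angles

Trunk deviation from the calibrated reference r₀ is defined per anatomical
plane as the difference of projected gravity angles:

    frontal = atan2(ĝ_z, ĝ_y) − atan2(r₀_z, r₀_y)
    lateral = atan2(ĝ_x, ĝ_y) − atan2(r₀_x, r₀_y)

wrapped to (−180°, 180°], positive frontal = forward lean, positive lateral
= lean to the wearer's right. Projected per-plane angles decouple the two
planes for small and moderate tilts, matching the independent per-plane
thresholds a therapist sets; they are not Euler angles of a single composed
rotation. Consistently, the simulator's ground-truth pitch and roll are
*defined* as the projected tilt angles of the noiseless gravity direction:
for a commanded (pitch, roll) the simulator constructs the unit gravity
direction ĝ ∝ (tan roll, 1, tan pitch) and realises it as the minimal
rotation carrying upright gravity onto ĝ (Rodrigues form), optionally
composed with yaw about the world vertical (yaw ∘ tilt). For the six
single-plane assessment movements the projected angle equals the rotation
angle exactly, so rotation matrices remain an independent oracle. Axial
(yaw) rotation leaves gravity unchanged; it is physically unobservable from
a static accelerometer, and the package asserts this invariance rather than
attempting to score rotation.

Calibration takes the normalised mean of the valid gravity estimates in a
window (default: the first 1 s of the stream, during which the wearer holds
their best-at-the-time posture) and persists until a new calibration is
performed.

## Feedback state machine

Configuration: per-plane thresholds (default 5°), tolerance before voice
guidance (default 3 s), praise interval (default 300 s), per-channel enable
flags, language (en/es/pt), optional re-entry hysteresis (default 0°, i.e.
plain thresholds), directive repeat period (default = tolerance), and an
RNG seed for the congratulation variant.

Rules: crossing either threshold turns the screen red and fires one
vibration pulse (transition-triggered, not continuous); if the wearer is
still out after the tolerance window, the directive opposite the dominant
deviation (larger |deviation|/threshold ratio, ties to frontal) is spoken
and repeated every repeat period; returning to posture turns the screen
green, speaks one of three congratulation variants chosen by the seeded
generator, and resets the praise clock, so "praise every 5 minutes" means
five *continuous* minutes in posture. With a channel disabled no event of
that channel is ever emitted; a silent-recording stage disables all three
channels while the state machine and 1 Hz angle log still run, which is how
a no-feedback control stage is recorded. All time comes from the sample
stream, making runs with identical input, config and seed byte-identical.

## Session logs and metrics

Logs use an OpenMHealth-style envelope (header: schema id/version, subject,
stage label, config snapshot, calibration; body: 1 Hz angle records and all
events). The reader validates structurally and names the offending field;
`read(write(x)) = x` holds for every valid log. The angle log is decimated
to one record per second regardless of input rate.

Metrics segment the per-second posture states into maximal constant-state
episodes. A *maintained position* is an in-posture episode lasting at least
`min_hold_s` (default 5 s — long enough to exclude pass-throughs, short
enough to count deliberate holds; configurable and reported in output). A
*corrective movement* is a completed out-of-posture episode (an OUT→IN
transition); the raw out-episode count is also emitted. Condition
comparisons offer both a paired t-test on per-subject (feedback on, off)
pairs — the within-subjects design — and Welch's unequal-variance t-test
computable from printed group summaries. Degenerate conventions: both SDs
zero with equal means gives p = 1; zero-variance nonzero paired differences
raise a degeneracy error rather than returning an infinite statistic.

## Simulator

A stage scenario emulates a ~10-minute rehabilitation stage: duration 600 s,
50 Hz sampling (a typical smartphone rate), Gaussian sensor noise with
SD 0.15 m/s² (a conservative consumer-MEMS figure), and trunk deviations
arriving as a Poisson process at 2/min with amplitudes uniform in 15–30°,
random plane and direction, and cosine ramps (1.5 s rise/return) so every
movement starts and ends upright. Correction latency is log-normal: with
feedback the out-of-posture hold lasts the engine's tolerance plus a draw
with median 4 s (σ = 0.4) after the first directive; without feedback the
wearer corrects on their own initiative after a median 15 s (σ = 0.5).
Longer uncorrected excursions consume stage time, so silent stages complete
fewer posture-hold cycles — the mechanism behind the measured group
difference. The simulated effect size is chosen to be clearly separable at
n = 40, comparable in direction (and order of magnitude) to the published
group summaries; it is not a fit to them.

What the simulator does *not* emulate: gait and upper-limb dynamics
(accelerations beyond gravity), sensor bias and drift, vest slippage,
axial-rotation scoring, or heterogeneous per-patient behaviour beyond the
latency distributions. Passing tests therefore demonstrate correctness of
the engine, logging and analysis pipeline under the stated motion model,
not clinical performance on real patients.

## Numerical and design notes

- Angle recovery is exact (≪1e-6°) at zero noise by construction of the
  tilt parametrization; the kinematic-agreement check runs unsmoothed
  (α = 1) since there is no noise to filter and the EMA's ~0.1 s lag would
  otherwise dominate the sub-0.1° comparison during ramps. The
  noise-robustness check (SD 0.3 m/s²) runs with default smoothing and
  stays under 2° RMSE including that lag.
- Episode boundaries fall on the first record of each new state; the final
  episode closes at the last record. Metrics are invariant to log
  re-serialization.
- Problem sizes in the automated checks (stage lengths of 30–600 s, study
  sizes of 6–40 subjects, 5 seeds for the recovery check) were chosen to
  keep the full suite fast while leaving the statistical conclusions
  unambiguous.
- Known limitations: no gyroscope/magnetometer fusion (so no yaw and
  coarser dynamics), per-plane angles distort near ±90° tilt (far outside
  the rehabilitation range), and the log schema is a single version with a
  version field reserved for forward evolution.
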