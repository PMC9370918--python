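# Methods

## The measurement problem

Repetitive palletizing consists of alternating picks and placings, each made
of a bending phase followed by a straightening phase, and the box is in hand
during only two of the four phase types (straightening out of a pick, bending
into a place). The pipeline quantifies how trunk and shoulder kinematics —
and the load moment on the shoulder — evolve over repeated sessions of such
work, keeping loaded and unloaded phases separate throughout.

Inputs are optical-capture marker trajectories for ten upper-body landmarks
(C7, T8, L5, sternum; front/back right shoulder; medial/lateral elbow
epicondyles; radial/ulnar wrist styloids) sampled at a fixed rate (50 Hz by
default), in meters in a right-handed global frame with +Z vertical. All
readers (TRC, wide CSV, optionally C3D) normalise units and axes to this one
internal convention.

## Kinematic model

All angles are sagittal-plane projections. The sagittal plane is built per
frame from the subject's own heading — the horizontal component of the
L5→sternum vector — because the subject walks and turns between sites; within
event windows the heading is stable, which is where the plane matters.

* **Trunk inclination** θ: signed angle between the sagittal projection of
  the L5→C7 spine vector and global vertical, positive when the spine tilts
  toward the sternum side (flexion), negative in extension. The sign is the
  sign of the forward-axis component of the projected spine vector; this is
  equivalent in intent to comparing cross-products of the spine vector with
  the sternum direction and with vertical, but has no degeneracy near
  upright.
* **Shoulder flexion** φ: signed angle between the sagittal projections of
  the upper-arm vector (glenohumeral centre → elbow centre) and the C7→T8
  trunk line, positive when the arm lies anterior to the trunk line. The
  glenohumeral centre is the midpoint of the front/back shoulder markers and
  the elbow centre the midpoint of the epicondyle markers; no regression
  joint-centre model is used. With this convention an arm hanging parallel
  to the trunk reads 0° in any posture, and a vertically dangling arm under
  a trunk flexed forward by α reads +α (at 90° of trunk flexion a dangling
  arm is at 90° of shoulder flexion).
* **Shoulder moment** m: the box is carried two-handed, so half the box
  weight (m_box·g/2, g = 9.81 m/s², configurable) loads the right
  glenohumeral joint. The box proxy is the wrist-marker midpoint; the lever
  arm is the signed forward-axis distance from the joint centre to that
  proxy, so the moment is zero exactly when the proxy sits on the vertical
  through the joint. The moment series is computed for every frame but only
  tabulated for loaded events.
* **Cumulative moment** CM = Σᵢ mᵢ·δt over an event, a left-Riemann sum over
  the event duration with δt the sampling interval. The quantity integrates
  newton-meters over seconds; it is reported under the conventional "Nm"
  label with this units note.

## Filtering

Marker coordinates are smoothed with a 4th-order low-pass Butterworth filter
at 10 Hz before any angle computation. Application is forward–backward
(zero-phase, odd-reflection padding of 3·(order+1) samples), because event
timing must not be lag-shifted; the stated order refers to the single pass,
so the effective magnitude order is 8. Angles are computed from filtered
markers, never filtered themselves.

## Event segmentation

1. **Troughs.** The vertical C7 coordinate is further low-passed at 1 Hz
   (same zero-phase design), leaving only the per-transfer dips. All local
   minima at least 5 s apart are found (transfer cycles last ~25 s and the
   pick and place dips within a cycle are ~8 s apart), and the 24 with the
   lowest filtered value — the ground-level bends — are kept, ties breaking
   toward earlier time. Each trough marks maximum back flexion: the end of
   bending and the start of straightening.
2. **Palletization subset.** The first 12 time-sorted troughs belong to the
   palletization half; the depalletization half is detected but discarded.
3. **Trough reconciliation.** The C7-height minimum and the trunk-inclination
   maximum are the same instant in principle; if the inclination argmax
   within ±0.5 s disagrees with the C7 trough by more than 0.2 s the argmax
   wins and the event is flagged.
4. **Boundaries.** The trunk-inclination rate of change is scanned outward
   from the trough inside a ±6 s window (half the nominal 12 s task cycle).
   The boundary is the last frame below 5°/s before (after) the sustained
   bending (straightening) motion; scanning first skips the sub-threshold
   plateau at the trough itself. If no such frame exists in the window, the
   window edge is used and the event flagged. The derivative is a central
   difference taken on a copy of the angle additionally smoothed at 2.5 Hz:
   with realistic marker noise the rate of an only-10 Hz-filtered angle has
   a noise floor of several deg/s, which would make a 5°/s threshold
   meaningless, while the bending motion itself lives well below 1 Hz and is
   untouched. The 5°/s default sits well below task peak trunk velocities
   (~45°/s) and well above the smoothed noise floor; both threshold and
   window are configurable.
5. **Labels.** Actions alternate pick, place, pick, … from the session start
   (the first bend is a pick at the storage side; overridable), each trough
   yielding a bending and a straightening event with the fixed load mapping
   (picking-bending unloaded, picking-straightening loaded, placing-bending
   loaded, placing-straightening unloaded). Repeat indices run 1–6 per
   action.
6. **Time normalisation.** Event windows are linearly resampled onto 101
   points (0–100 % in 1 % steps, the movement-science convention).

## Metrics

Per event (raw frames, inclusive of boundaries, so summaries are
duration-weighted as recorded): total time; time to each signal's maximum
(first attaining frame on ties); time to first crossing of 80 % of the
within-event maximum (first upward crossing for both phases); max, mean and
median of each angle; peak, mean and cumulative moment (loaded events only —
requesting moments for an unloaded event is an error, not a zero).

Per event type and participant (time-normalised profiles, averaged over the
≤ 6 ground-level repeats first): the **enclosed area** between the mean trunk
and shoulder curves, computed as the trapezoidal integral of their absolute
difference over 0–100 % divided by 100 — i.e. the mean absolute separation,
in degrees; the percent-time offsets between the two signals' peaks and 80 %
crossings; and movement variability as the n−1 SD of per-repeat maxima plus
the mean over the 101 points of the per-point SD across repeats.

## Statistics

Event-level metrics are averaged within (participant, session, event type)
cells; participant means of session 1 and session 3 are compared with
two-sided paired t-tests, t = mean(d)/(sd(d)/√n), df = n−1 (n = 9
participants, df = 8), significance at α = 0.05. No multiplicity correction
is applied by default — many tests run at nominal α, as is conventional in
this literature — but Holm's step-down procedure is available behind a flag.
Session 2 is ingested and excluded from the comparison.

## The synthetic cohort

Real sessions of this protocol are not publicly available, so the package
carries a forward-kinematic generator whose defaults *are* the protocol
conditions: 24 transfer cycles (12 per half) at 50 Hz; 12 s of pick + 8 m
carry + place per cycle plus a 13 s unloaded return, making ≈ 10 min per
session (the protocol's printed pace, box count and session duration cannot
all hold simultaneously, so the task cycle and the return walk are separate
parameters); six ground-level picks and six ground-level placings per half;
a 10 kg box.

Each bend–straighten pair is a raised-cosine bell (C¹, fully described by
peak and time-to-peak) for both angles, the shoulder peaking 5 % of the
bending duration before the trunk by default. Ground-level events draw trunk
peaks from N(60°, between 5°, within 3°) and add an 8 cm whole-body squat;
upper-layer events draw from N(25°, 4°, 2°), so ground dips are ~0.33 m deep
against ~0.05 m and the lowest-24 rule is meaningfully exercised. Timing and
shoulder-angle distributions default to the emulated study's session-1 group
statistics — time to maximum back inclination in picking-bending
N(1.92 s, SD 0.32 s), median shoulder flexion 54.9° ± 9.7° in loaded
placing-bending and 23.1° ± 10.3° in loaded picking-straightening — with
each printed SD split into a between-participant and a within-participant
component whose squares sum to it (e.g. 0.25² + 0.20² ≈ 0.32²).

Two generator choices deserve emphasis:

* **Median calibration.** The shoulder peak is not drawn directly. A target
  for the *measured* within-event median shoulder flexion of the loaded
  phase is drawn, and the peak solved from the profile's shape over the
  window a threshold-based detector reports (trough to threshold-crossing).
  Because the profile is affine in its peak, the solution is closed-form.
* **Two truth boundaries.** A raised cosine has zero velocity at its onset,
  so "the event boundary" is definitionally ambiguous. The truth table
  records both the zero-velocity onset/offset (`start_s`/`end_s`) and the
  instants where the true, noise-free trunk velocity crosses the configured
  rate threshold (`start_thr_s`/`end_thr_s`). Recovery tests measure the
  segmentation machinery against the threshold-crossing truth, which
  isolates detection error from the irreducible definitional offset
  (~0.07–0.14 s for default profiles).

The generator articulates only the sagittal chain under a per-half heading
(+Y out, −Y back, with a smooth turn between halves); mediolateral marker
offsets are constant; the arm is straight (wrist collinear with the upper
arm); there is no gait oscillation, no physiological fatigue, and upper
layers exist only as shallower dips. Consequences worth knowing: with a
straight arm and low shoulder flexion under deep trunk flexion the wrist can
sit posterior to the shoulder, so picking-straightening moments come out
negative in the synthetic cohort — real workers flex the elbow to keep the
box anterior. Passing recovery tests therefore demonstrate that the pipeline
measures what the generator encodes; they do not certify performance on real
capture data with soft-tissue artefact, occlusions or off-sagittal motion.

Cohorts draw per-participant distribution means (between-participant SD),
anthropometry with 4 % multiplicative jitter, and apply configurable
session-3 mean shifts (half for session 2). The default shifts emulate the
reported first-vs-last changes: picking-bending time-to-peak −0.11 s and
loaded-event median shoulder flexion −6.9°/−5.2°.

## Numerical choices and degenerate inputs

* Occlusion gaps (NaNs) are linearly interpolated up to 0.2 s; longer or
  boundary-touching gaps are hard errors naming marker and interval.
* Heading frames with < 1 µm of horizontal L5→sternum component inherit the
  previous frame's heading; at frame 0 this is an error.
* Ties in maxima resolve to the first attaining frame everywhere.
* Zero-variance paired differences raise rather than returning ±inf.
* Filtering requires series longer than the reflection pad (3·(order+1));
  cutoffs at or above Nyquist are rejected at construction.

## Problem sizes

Default test and reproduction runs use full-length sessions (≈ 600 s, 30 001
frames): one default session for the trough/pace accounting, a 9-participant
single-session cohort for the recovery checks, 20 seeded noisy sessions for
the label/boundary robustness suite, and 2000 simulated null replicates for
the type-I calibration of the paired test. These sizes keep the whole suite
in the tens of seconds on one core while leaving every count at its
protocol value.
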