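# Methods

## Problem setting

A single inertial node (3-axis accelerometer, gyroscope, optionally
magnetometer; 100 Hz to SD card) is worn at the shank/ankle of a person
with Parkinson's disease. From this one sensor the toolkit detects two
expressions of freezing of gait: trembling-type freezes (legs oscillate at
3–8 Hz while the feet stay planted) and festination (cadence rises while
stride length collapses, typically announcing a freeze). Clinician video
labels with severities green (slight gait modification), orange (gait
modification with fall risk) and red (blocked gait) are the reference the
detectors are scored against.

## Sagittal projection (`fogkit.kinematics`)

Walking dynamics live mainly in the sagittal plane, so all downstream
processing uses three derived channels: the angular rate ω about the
medio-lateral axis and the gravity-free forward/vertical accelerations.

* **Gravity** is the mean accelerometer vector over a quiet-standing
  calibration window — declared in config, or auto-detected as the 2 s
  window minimising total acceleration variance (RMS deviation must be
  < 0.3 m/s², else a calibration error is raised; likewise if the mean
  specific force is < 5 m/s², which indicates free fall or corrupt data).
  Subtracting the window's mean magnitude rather than a nominal 9.81
  absorbs accelerometer scale/bias error.
* **Medio-lateral axis**: the principal component of the gyroscope signal
  (shank rotation during gait is overwhelmingly about this axis),
  orthogonalised against gravity. Sign conventions are data-driven: ω is
  oriented so its distribution is positively skewed (swing pulses point
  up), and the forward axis — the cross product of medio-lateral and
  vertical — is flipped if forward acceleration anti-correlates with the
  angular acceleration of the swing.

This static-calibration approach deliberately avoids continuous
orientation tracking (quaternion filters): over desk-scale recordings the
sensor-to-segment alignment is constant, and the magnetometer is left
unused by default because indoor fields are unreliable.

## Stride segmentation and stride length

Strides are cut at successive mid-swing peaks of ω (`scipy.signal.find_peaks`,
prominence ≥ 0.5 rad/s). An inter-peak interval is a stride only if its
duration lies in [1/C_max, max_stride_s] = [0.2 s, 2.5 s]: shorter
intervals cannot be gait cycles at the cadence ceiling C_max = 5 strides/s
(the segmenter never reports strides shorter than 1/C_max), and longer
ones are gait interruptions (stops, freezes), not strides. Cadence is the
reciprocal of stride duration, in strides/s throughout (no conversion to
steps).

Stride length comes from drift-corrected integration inside each stride:

1. initial forward velocity v₀ = ω(start)·r, with r the shank lever arm
   (config, default 0.4 m) — a rigid-rotation model of the leg at
   mid-swing;
2. v(t) = v₀ + ∫ a_fwd dt (trapezoidal);
3. the terminal velocity is forced to the gyroscope estimate ω(end)·r by
   subtracting a linear ramp (the standard de-drift for one integration
   span);
4. Lₙ = ∫ v dt, clamped at 0 from below.

Indices are 0-based and half-open throughout; segmentation is fully
deterministic.

## Freeze Index (`fogkit.freeze_index`)

Each analysis window is Hann-tapered and its one-sided periodogram
integrated by the trapezoidal rule over the freeze band [3, 8] Hz and the
locomotor band [0.5, 3) Hz; FI is the squared ratio of the two areas. The
Hann taper controls leakage across the shared 3 Hz edge; the boundary bin
is assigned to the freeze band (configurable). The window is 6 s by
default, sliding at 10 Hz (hop 0.1 s) — fine enough to localise 1–2 s
events; only instants with a full window of data are reported. A shorter
window raises sensitivity to brief freezes (the 4 s profile used in the
worked example and the end-to-end tests); a longer one low-passes them
away. A `squared: false` switch yields the plain band-power ratio for
comparison with the original spectral index.

When the locomotor area underflows (`eps` = 1e-12 — quiet standing or a
constant signal) the ratio is a 0/0 artifact: the window gets a capped
sentinel value (1e6) and a flag, and flagged windows are excluded from
event detection. Without this, noise-only standing would score
FI ≈ (5 Hz / 2.5 Hz)² ≈ 4 — far above any sensible threshold — purely
because the freeze band is twice as wide as the locomotor band.

Threshold calibration follows the standing-epoch recipe: per epoch take
the peak FI, return mean + 1 sample SD (n−1) of the peaks; at least two
epochs are required for the SD to exist.

## FOG criterion and event logic (`fogkit.fogc`, `fogkit.events`)

FOGCₙ = Cₙ·L_min / (C_max·(Lₙ + L_min)) is evaluated per stride, exactly
and without clamping; with C_max = 5 strides/s and L_min = 0.05 m it is
strictly increasing in cadence, strictly decreasing in stride length, and
bounded by 1 (attained at Cₙ = C_max as Lₙ → 0). It is kept stride-indexed
rather than resampled to uniform time: during a complete freeze or quiet
standing no strides exist and the criterion is undefined — extrapolating
would invent data exactly where gait is interrupted.

Event extraction:

* **FI**: maximal runs of above-threshold unflagged windows, each window
  contributing ± half a hop; runs closer than `merge_gap_s` (0.5 s) merge;
  events shorter than `min_duration_s` (0.5 s) are dropped as spectral
  blips (clinically, freezes last ≳ 1 s).
* **FOGC**: runs of above-threshold strides; single-stride events are
  legitimate. A stride-free gap of at least `freeze_gap_min_s` (1 s)
  immediately after an above-threshold stride is bridged into the event,
  up to the next stride or the end of the data: the criterion fired and
  gait then stopped — that interruption *is* the freeze the criterion
  anticipated. When strides resume above threshold the bridge fuses both
  runs into one event; when they resume below threshold the event ends at
  the resumption. A gap following a *below*-threshold stride (normal
  stop, rest) is never bridged.

Scoring is overlap-based with a symmetric tolerance (`tol_s`, default
1 s): an annotation is detected if any detection overlaps its widened
interval; a detection overlapping two annotations credits both (nearby
clinical episodes are distinct events); a detection overlapping none is
one false positive. Detected + missed = annotated per severity by
construction, and widening the tolerance can only increase detected
counts. The report table has the severity × {annotated, FI, FOGC} shape
used in clinical FOG studies. Whether false positives should be counted
per event or per unit time is a genuinely open choice; per event is
implemented.

## Synthetic gait (`fogkit.synthetic`)

The generator renders scenario scripts (ordered walk / festination /
tremble / stand segments) into raw sensor frames with exact ground truth.
Design goal: the oracle must be exact by construction, not itself an
estimate.

* ω is a train of half-sine mid-swing pulses (peak 4 rad/s, swing 35 % of
  the cycle) at the prescribed, possibly ramping cadence; pulse centres sit
  at half-integer gait phase. Ground truth counts pulse-to-pulse strides
  (K centres → K−1 strides), the same convention the segmenter uses, and
  includes the stride spanning two adjacent gait segments (its true length
  is the velocity integral, since no length is prescribed for it).
* The forward velocity is r·ω plus, inside each stride, a sin² bump scaled
  so the stride's displacement equals the prescribed length exactly (the
  bump vanishes at the stride boundaries, so boundary velocities obey the
  same v = ω·r model the estimator assumes); a_fwd is its numerical
  derivative.
* The vertical channel oscillates at the step frequency (2 × cadence)
  capped at 2.5 Hz. The cap keeps the fundamental one full spectral
  main-lobe width (0.5 Hz for the shortest, 4 s, analysis window) inside
  the locomotor band while the cadence ramps to 3 strides/s. This encodes
  the clinical observation the toolkit is built around: festination
  accelerates stepping (reported step rates ≈ 2.8 ± 0.2 per second) but
  does not move vertical power into the freeze band, which is precisely
  why spectral detectors miss it.
* Tremble segments have no swing pulses (no strides — the feet stay
  planted) and add a freeze-band sinusoid (6 Hz, 1.5 m/s²) to the vertical
  channel; stand segments are gravity plus noise only.
* Gravity (9.80665 m/s² on the body z-axis) is added, an optional fixed
  mounting rotation maps body to sensor axes, and white Gaussian noise
  (per-channel, `noise_sd`) is applied last. Identical configuration and
  seed give bit-identical output.

The presets are the study conditions used throughout the tests: healthy-ish
walking at 0.9 strides/s × 1.4 m (FOGC ≈ 0.006, below the 0.008
threshold), a 12 s trembling freeze inside walking (twice the 6 s FI
window, the rule of thumb for the shortest reliably detectable event), and
the festination-into-freeze sequence (ramp 1 → 3 strides/s, 1 → 0.1 m,
then 8 s trembling). All presets are noise-free — parameter-recovery
tolerances then measure estimator error, not noise — and start with 3 s of
quiet standing for gravity calibration.

What the generator does **not** model: sensor bias/drift and scale error,
turning, doorway/dual-task context, double-support micro-dynamics,
harmonic-rich real spectra, soft-tissue artifact. Passing tests therefore
demonstrate internal consistency of the estimators and detectors under
the stated signal model, not clinical performance; the original cohort's
episode counts are not reproducible without the patient recordings and no
attempt is made to match them.

## Numerical choices and edge cases

* Recordings must be strictly increasing, uniformly sampled (|Δt − 1/fs| <
  1 µs), NaN-free, ≥ 2 samples, fs ≥ 20 Hz (freeze band resolvable with
  margin); the loaders repair nothing — malformed input raises. On-disk
  units may be g / deg/s; internally everything is m/s² and rad/s. CSV
  round-trips channels to < 1e-9 (12 significant digits) and metadata
  exactly.
* FI: the band-power integral uses inclusive edges, except the locomotor
  band's upper edge (half-open) so the 3 Hz bin is counted once.
* Stride length: numerically tiny or backward strides clamp to Lₙ = 0;
  FOGC(Lₙ = 0) is finite by construction (L_min in the denominator).
* Stride cutting with zero or one peak yields zero strides — a valid
  result (standing, trembling), not an error.
* Detection thresholds (FI 0.1, FOGC 0.008) follow the published
  figure-profile values; both are per-patient settings in practice, and
  the FI one can be recalibrated from standing epochs. How a per-patient
  FOGC threshold should be derived is unspecified in the source method;
  it is exposed as a plain parameter.
* Problem sizes in the test suite (10–33 s scenarios, ≤ 100 k-point
  detector arrays, 1024-point DFT oracle windows) keep the full suite in
  a few seconds while exercising every code path; the generator and
  pipeline scale linearly for longer recordings.
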