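# Methods

## Problem

Game engines prepare frames ahead of display and give no guarantee about
when a drawn event actually reaches the subject's eyes.  For neuroscience
experiments that relate behavior to neural recordings this is fatal unless
corrected: at 60 Hz, a naive "game time" stamp can be tens of milliseconds
early relative to the photons.  `domekit` implements the offline half of a
dome-VR rig's timing story: a plain-text session log with enough timing
information to reconstruct on-screen times, the conversion itself, a
photodiode-based verification of that conversion, the projection geometry
of a hemispherical dome display, and receptive-field mapping schedules
expressed in dome coordinates.  A session simulator generates every
artifact (log, 16-bit marker channel, 30 kHz photodiode trace, ground
truth), so the full pipeline is testable without hardware.

## Timing model

Let `P = 1/f` be the refresh period (default `f = 59.952 Hz`).  Frame `k`
is handed to the swap chain at high-resolution (QPC) time `F_k`, scanned
out `n_p` refresh periods later (`n_p = 2` for the dome's multi-camera
rendering), and shown by the projector after a further fixed display delay
`d` (default 18 ms).  Its true display time is

    D_k = F_k + n_p * P + d.

The log records, for each frame from the third game frame onward, the
game-thread time at which its preparation started and `F_k`.  An event
logged at game time `t` belongs to the frame whose preparation interval
(half-open on preparation start times) contains `t`, and its screen time is

    screen(t) = F_k(t) + n_p * P + d,

i.e. the frame's *actual* handover timestamp plus the fixed delay
`n_p * P + d` (51.360 ms for the default configuration).  Because a stuck
frame (a "frame skip", shown for `2P`) stalls the game thread and the
handover tick together, the doubled interval is present in `F_k` itself and
converted times follow skips exactly; no nominal-period arithmetic crosses
a skip.  This is the package's resolution of an ambiguity in how the
graphics timestamp could be anchored (the frame's own scanout vs. the frame
currently displayed during preparation): anchoring on the handover tick is
the only choice for which the fixed-delay formula and exact skip-following
hold simultaneously, and the simulator defines its ground truth the same
way.

Event markers carry both a game-thread time and a QPC timestamp; the pairs
anchor a piecewise-linear monotone map between the two clocks (linear
extrapolation at the edges; no drift model is assumed beyond piecewise
linearity).  Events logged before the first tabulated frame are converted
through this map plus the fixed delay and flagged approximate.

Skip detection thresholds the per-frame on-screen interval at `1.5 P`, the
midpoint between one and two periods; flip jitter in real systems is far
below `P/2`, so the threshold is not sensitive.

## Log dialect

Tab-separated lines of `time, object id, line type, payload...` after a
`# key: value` header; all reals print with 7 decimals, so the dialect's
time resolution is 0.1 µs (two orders of magnitude below one 30 kHz
sample).  Line types and payload shapes are listed in the
`domekit.timedlog` module docstring.  Parsing is streaming: memory use is
constant plus whatever the caller retains, with one exception — screen-time
conversion necessarily first builds a per-frame table (two floats per
frame) from a dedicated pass.  The abbreviated log is a verbosity-filtered
subset (0: states + markers; 3: identical to the continuous log).
Unmatched state exits are errors; states still open at end-of-file are
returned as open intervals under a warning, since truncated sessions are
normal.

Behavioral performance is summarized as outcome-state counts plus the
proportion of correct outcomes in a sliding window of the last `w` trials
(default 20), the standard session chart.

## Photodiode verification

The flicker object steps through brightness `1, 0.3, 1, 0` on each running
frame (0.5 while idle, black during pauses) and emits a marker at every
switch.  Verification analyzes the 1 → 0 transitions: the trace is filtered
with a 500 Hz 4th-order Butterworth low-pass applied forward-backward
(zero-phase, so the filter contributes no delay), and the transition time
is the extreme of the first difference inside a ±5 ms window around the
predicted screen time, sign-selected by polarity.  A transition is declared
missing when that extreme fails to beat five times the median absolute
first difference of the window's flanks, or fails to dominate the
opposite-polarity extreme (filter ringing of a wrong-polarity edge
otherwise passes a noise floor).  Residual = measured − predicted, in ms;
percentiles use linear interpolation between order statistics.

One correction matters.  For an instantaneous edge the zero-phase filter is
symmetric and the max-change time is unbiased; for a first-order (RC)
photodiode rise with time constant τ the filter smears the one-sided
derivative and shifts its argmax late by a deterministic amount (≈0.33 ms
at τ = 0.5 ms, 500 Hz, 30 kHz).  `verify_session` computes this detection
latency from a noiseless forward model of the instrument chain (the same
discrete RC stage and the same filter applied to an ideal step) and
subtracts it, so residuals measure display timing rather than photodiode
dynamics.  τ is a parameter (default 0.5 ms; 0 disables the correction);
misestimating τ by a factor of two changes the correction by well under
0.1 ms.  The raw per-transition statistic (`transition_residual`) is left
uncorrected for callers who want the unmodeled quantity.

Clock plumbing: the marker channel records each marker's acquisition
sample index; the log records the same markers' QPC timestamps.  Matching
them one-to-one gives a piecewise-linear QPC → sample map through which the
predicted screen times are taken into the trace's time base.

## Simulator

`simulate_session` draws handover ticks one period apart, doubles an
interval with probability `skip_probability` per frame (default 0.02),
stalls for injected pauses (screen black; the resume frame is forced
stuck, reproducing pause-induced skips), and emits: FRAME lines from the
third frame, a marker per brightness switch at a random phase within the
frame, INPUT/POSITION lines for a random-walking test object, and state
enter/exit lines (plus optional trial-outcome sequences for performance
analyses).  The photodiode trace maps brightness affinely to voltage
(black 0 V, full 2 V — the scale is irrelevant to timing and
configurable), applies a discrete RC rise (τ default 0.5 ms), resamples at
30 kHz and adds Gaussian noise of sd `noise_sd_fraction × amplitude`
(default 2%).  All randomness flows from one seeded NumPy PCG64 generator;
the seed is written into the log header, and identical parameters produce
byte-identical artifacts.  Log records are quantized to the dialect's 7
decimals at creation, so the in-memory session equals its parsed file.

Default problem size: 4400 frames (~73 s of session, 1100 analyzed
transitions, a 2.2 M-sample trace), which keeps a full
simulate → parse → verify cycle under a few seconds while exceeding the
thousand-transition scale at which the headline fractions are quoted.

What the simulator does *not* emulate: real projector/photodiode transfer
functions (PWM modulation, amplifier dynamics beyond first order),
marker-to-acquisition latency (a jitter knob exists, default 0), clock
drift between game and QPC clocks (the map supports it; the generator
injects only constant offsets), and input-device latency.  Passing the
synthetic verification therefore shows the *pipeline* is correct and
precise to sub-sample level under realistic noise, not that any particular
hardware achieves it.

## Dome geometry

Axes: +X forward, +Y right, +Z up.  Dome coordinates are azimuth
(positive right) and elevation (positive up) at fixed radius (60 cm
physical dome, 250° coverage); `(0, 0)` is front-center, so dome
coordinates equal visual angles for a centered, forward-gazing subject.
Conversions are the standard spherical forms; azimuth is reported in
(−180°, 180°], elevation in [−90°, 90°]; the zero vector is rejected and
azimuth at the poles is conventionally 0.

The fisheye image uses the equidistant law — radial image distance
`0.5·θ/θ_max` from center `(0.5, 0.5)`, with `θ_max = 125°` on the image
circle's rim — the convention of the mirror-dome projection method this
geometry follows; the u axis points right, v up.  The five-camera rig
(square 90° frusta facing front/left/right/up/down) covers every direction
within 125° of forward, with only a rear gap; composing face projection,
face-pixel reconstruction and the fisheye law reproduces the direct
mapping to machine precision, and seam consistency at face boundaries is
exact because adjacent faces see the same ray.

Warp meshes are regular screen-space grids of `x y u v intensity` nodes
(text files: projection-type integer, `nx ny`, then row-major nodes).
Application bilinearly interpolates texture coordinates and intensity per
output pixel, then samples the source bilinearly; nodes with texture
coordinates outside [0, 1]² are invalid and their cells render black
(transparent in the file convention).  Mesh *generation* for a specific
mirror/dome pair is a calibration task outside this package's scope; only
loading and application are implemented.

## RF mapping schedules

All three paradigms are pure functions of parameters and seed and emit
per-frame events in dome coordinates, every element within the 125°
coverage:

* **Bar sweep** — a great-circle strip of fixed angular width; the center
  advances `speed/frame_rate` degrees per frame along the sweep direction
  (parameterized in the azimuth-elevation plane), covering `extent`
  degrees centered on the origin.  The logged quantity is the per-frame
  strip center.
* **Flash grid** — circular Gaussian blobs (truncated at 3σ) flashed once
  per repetition per grid location in a seed-determined order,
  `flash_frames` on followed by `gap_frames` off.
* **Sparse noise** — `squares_per_frame` distinct lattice sites per frame
  (sampling without replacement within a frame), independent uniform
  polarity from {black, white}, lattice anchored at (0, 0) with uniform
  spacing over an intermediate-gray background.

The generator is NumPy's PCG64, named and versioned in schedule headers,
since cross-run reproducibility of the stimulus sequence is part of the
logging contract.

## Numerical choices

* Percentile definition: linear interpolation between order statistics.
* Analysis window ±5 ms: adjacent flicker transitions are one frame
  (≈16.7 ms) away, so exactly one transition falls inside a window even
  across a single skip.
* A luminance change at time `t` first affects sample `round(t·fs)`
  (round-half-up), and a measured transition is timed at the arrival
  sample of its extreme difference; residual quantization is therefore at
  most one sample (0.0333 ms at 30 kHz).
* Screen-time conversion is exact arithmetic on the frame table (≤ 1e-9 s
  against in-memory truth); through a serialized log the bound is the
  dialect quantum, 1e-7 s.
* Tie-breaking in the camera rig: the covering face with the largest
  forward component, in a fixed face order.

## Known limitations

* The marker channel is assumed loss-free and order-preserving; dropped
  TTLs make `verify_session` raise rather than resynchronize.
* The detection-latency correction models a first-order rise only; a
  strongly non-exponential photodiode would leave a residual bias (the
  uncorrected statistic is available).
* The warp applier assumes tensor-product node grids, which covers the
  mesh files this ecosystem produces but not fully unstructured meshes.
* `parse_log(convert=True)` needs a seekable source (it reads the file
  twice); pipe input requires `convert=False`.
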