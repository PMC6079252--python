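# Methods

This note records the models behind `sbemctl`, the parameter choices that
matter, what the virtual instrument does and does not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frames and stage calibration

Two planar frames: the SEM frame (image-like, microns, x right / y down)
and the motor frame the stage accepts. The calibration matrix has the
scaled, rotated motor unit vectors as rows,

    M = [  sx·cos(ax)   sx·sin(ax) ]
        [ -sy·sin(ay)   sy·cos(ay) ],

angles counterclockwise from the SEM axes. This convention is declared
once so persisted calibrations are unambiguous; an installation whose axes
follow the opposite sign convention simply calibrates to negated angles.
The forward map is defined for any angles; inversion requires
det M = sx·sy·cos(ax − ay) ≠ 0, i.e. the motor axes must not be parallel,
and a singular matrix raises the stage-calibration error only where the
inverse is actually needed.

Calibration estimation is ordinary least squares per motor axis on
(SEM displacement → motor displacement) pairs: motor_x = p·sx_d + q·sy_d
gives scale_x = √(p² + q²), angle_x = atan2(q, p), analogously (with the
sign convention) for the second row. Two non-collinear displacement pairs
determine the fit; on noise-free inputs it inverts the forward transform
to machine precision, which the simulator end-to-end test checks through
the motor-only stage interface.

Tile grids are axis-aligned (rotated grids are out of scope): pitch =
(frame − overlap)·pixel_size per axis, negative overlap meaning a gap.
Tile indices are 0-based (row, col), stored positions are frame centers,
pixel rectangles are 0-based half-open.

## Debris detection

Each newly acquired overview is compared against the **last accepted clean
overview** of the same region (not the immediately preceding one), so slow
drift never accumulates into false positives; the very first overview is
taken as the confirmed-clean reference. Three detectors:

* **quadrant_meansd** (default): the detection region splits into four
  quadrants (odd extents: the extra row/column joins the lower/right
  quadrants); debris iff any quadrant's |Δmean| > mean threshold **or**
  |ΔSD| > SD threshold. OR is the data-protecting combination. To keep a
  single machine-readable decision pair in the report, SD differences are
  expressed in mean-threshold units (|ΔSD|·mean_thr/sd_thr) inside
  `max_diff`, so `debris_detected ⇔ max_diff > threshold` always holds
  while the raw eight statistics remain in `per_region_diffs`.
* **histogram**: total variation distance ½·Σ|p_i − q_i| between
  unit-normalized gray-level histograms (256 bins), range [0, 1].
* **pixel_diff**: fraction of pixels with |Δ| strictly greater than a
  per-pixel delta.

All thresholds are strict and are starting points to be tuned per sample;
the shipped defaults on 8-bit images are mean 10, SD 10, TV 0.10, pixel
Δ 25 with fraction 0.05. When detection-region restriction is enabled, the
region is the bounding box of all active-tile footprints projected into
overview pixels, falling back to the configured region when no grid has
active tiles.

On detection the engine lowers the sample by the sweep depth (default
70 nm) and sweeps the knife, re-acquires and re-tests, never exceeding the
configured maximum number of sweeps; it then either pauses or continues
with debris, per policy. Every event is logged (slice, overview, method,
max_diff, threshold, sweeps).

Limitation (also visible at simulator scale): the quadrant statistics
dilute when a chunk straddles quadrant boundaries or is small relative to
a quadrant — the 100 %-detection property holds for chunks covering ≥ 10 %
of the detection region with ≥ 3× the mean threshold in contrast and lying
within one quadrant. Micron-scale flakes are not guaranteed to be caught.

## Focus control

Working distance (WD, mm) is the control variable. Sharpness is
normalized gradient energy — mean squared first difference along both axes
over the squared image mean — a contrast-invariant artifact choice; the
"best focus" contract is defined against the simulator's known true WD,
not a particular metric value.

**Through-focus series**: n (odd) frames of 512×384 px at
wd_center + k·step, each acquired exactly once to minimize dose; the
sharpest frame wins, optionally refined to sub-step precision by parabolic
interpolation of the three scores around the peak (clamped to ±½ step).

**Focus gradient**: the unique plane WD(x, y) = a·x + b·y + c through
three non-collinear reference measurements, evaluated at every tile
center; it reproduces its inputs to 1e−9 mm by construction. Per-tile WD
precedence: explicit per-tile override > gradient plane > global focus
state. On the simulator the knife tilt (default 0.02/0.01 mm per mm) is
recovered by three through-focus measurements to well under one focus step
at a held-out position.

**Heuristic autofocus**: the cited continuous method is autocorrelation
based; the algorithm here is an extremum-seeking controller on the
half-width (at half maximum) of the autocorrelation central peak. White
detector noise contributes only to the zero lag, so the peak is normalized
at lag 1 and measured from there — without this the width estimate
collapses at strong defocus. The correction magnitude is
gain · (width − best width seen), clamped to ±max_step (defaults
5e−4 mm/px and 0.002 mm, tuned once on the simulator), and the sign flips
whenever the width grew since the last step. At focus the excess is zero
and the state rests. A 0.01 mm focus jump recovers ≥ 95 % of the in-focus
sharpness within 10 slices; linear drift is tracked within three slices'
worth of drift. Astigmatism values are carried as state but have no
optical model.

Scheduled (vendor) autofocus is represented by a simulator oracle that
returns the true WD plus a configurable residual; focus and stigmation
passes can be offset against each other via modular offsets
((slice − offset) mod interval = 0).

## The acquisition cycle

Per slice, in order: remote-pause sentinel check; due overviews with the
debris loop; scheduled autofocus; due grids' remaining active tiles in
row-major order (grids ascending by id); mirror sync; one cut; counter
advance. The order within the cycle and the acquisition order are fixed
for determinism (resume tests depend on it). Already-acquired tiles and
overviews of the current slice are remembered across pauses, so resuming
continues at the correct grid position and every scheduled tile is written
exactly once — a property tested over randomized fault schedules.

Instrument operations retry up to three total attempts, logging a warning
per failure; exhaustion maps to a three-digit error code (first digit:
1 communication, 2 microtome/stage, 3 SEM, 4 I/O, 5 acquisition/
inspection, 6 user-defined), pauses the run, and appends to the
notification log (the stand-in for e-mail alerts; transports are out of
scope). Monitoring failures (tile mean/SD jump beyond strict thresholds),
inspection failures (unreadable, wrong size, uniform, statistics out of
range) pause likewise; user-supplied predicates may only select or discard
accepted images (to save storage), never pause, and a discarded file is
deleted only after the decision is logged.

Estimates: dose D = I·t/(e·A) in e⁻/nm² (reported as a min–max range over
grids); duration = Σ pixels·dwell + per-tile stage-move overhead
(default 2 s) + per-slice cut overhead (default 12 s, both site-specific);
storage = exact scheduled bytes.

## The virtual instrument

The phantom is a procedural 3D scalar field: two banks of random cosine
waves — micron-scale (2–20 µm wavelengths) for overview-visible structure
and sub-resolution fine texture (50–400 nm) that gives tiles their
sharpness — plus an ellipsoidal "specimen" of distinct texture and +40
gray offset whose cross-section changes with depth, so adaptive-tiling
scenarios have an irregular, z-varying target. Axial wavelengths are
2–10 µm, so consecutive 25 nm slices are strongly correlated, as real
block faces are. Cutting and sweeping only advance the face depth.

Imaging samples the field at the current face, composites active debris
patches additively, blurs with a Gaussian whose sigma is a **physical
length** (default 15 000 nm per mm of WD error, divided by the pixel
size — defocus that ruins a 10 nm tile barely touches a 150 nm overview),
and adds Gaussian noise with variance ∝ 1/dwell (std 8/√µs). These
constants are simulator parameters, not claims about electron optics; the
simulator has no charging, no cutting-physics, no astigmatism model.
Everything downstream of the seed is deterministic given the command
history, and the command log is the oracle the engine tests read.

The stage exposes motor coordinates only, through a hidden calibration
(the scenario default: angles 30°/28°, scales 1.02/0.98). The
trigger-file protocol (input file with one command and ≤ 2 parameters,
empty trigger file, one-line response; 0.1 s poll) carries the microtome
commands, mirroring the split control path of real systems where frames
flow through the vendor acquisition API instead; the in-process backend is
the default for speed and satisfies the same contract.

## Data handling conventions

Tiles:
`tiles/g{GGGG}/t{RRRR}x{CCCC}/{stack}_g{GGGG}_t{RRRR}x{CCCC}_s{SSSSS}.tif`,
overviews analogously — a declared scheme isolated behind one
format/parse pair (the naming bijection is property-tested). TIFFs are
grayscale and uncompressed (8-bit default). Metadata is line-delimited
JSON, one self-contained record per written file, so a crash loses at most
one line. The mirror copies files and marks them synced only after size
and checksum match; mirror failure warns and never pauses (the primary
store is authoritative). TrakEM2 export uses the tab-separated import-text
form (path, x px, y px, section), offsets anchored at the dataset-minimum
SEM position (the anchor choice is declared; a stage-origin anchor would
differ by a constant), one resolution per export.

## Problem sizes and defaults in the validation scenarios

The bundled scenarios are desk-scale by design: 64×48 px tiles in 2×2
grids, 200×150 px overviews, 3–100 slices — small enough that the whole
suite and the acceptance script each run in well under a minute of compute
per scenario, while still exercising every control path (the scale of a
production stack changes counts, not logic). Debris chunks in the
pipeline scenario are 8×6 µm at 60 gray levels of contrast with removal
probability 1, landing on ten fixed slices of 100. Fault schedules fail
three consecutive acquisition attempts starting at a random call index.
All randomness is seeded.

## Known limitations

* The autofocus controller is an interpretation of the cited
  autocorrelation approach, not a reimplementation of its exact math; its
  convergence constants are tuned to the simulator's blur model.
* Quadrant debris detection weakens for chunks straddling quadrant
  boundaries and for micron-scale flakes.
* Motor-speed (timing) calibration, rotated grids, astigmatism optics,
  e-mail/remote transports, and GUI features are out of scope; passing
  simulator tests bounds algorithmic correctness, not real-instrument
  behavior (blur/noise constants, charging, and mechanical drift differ).
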