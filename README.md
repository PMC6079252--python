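# sbemctl

Headless acquisition control for **serial block-face electron microscopy
(SBEM)** — the repeated cycle of imaging a resin-embedded sample's block
face and cutting away an ultrathin slice with an in-chamber diamond knife.
Long SBEM runs (days to months) are destructive and unattended, so the
engine's job is process control: detect debris on the block face and sweep
it away, keep the beam focused on a tilted surface, acquire only the tiles
that contain tissue, monitor every image for sudden quality changes, retry
transient faults, and pause safely — never losing data and never scanning a
tile twice.

The package is a library plus a small CLI, exercised end-to-end against a
bundled **virtual instrument** (procedural 3D phantom, motorized stage with
rotated/scaled axes, knife, defocus-blurred noisy detector), so every
control algorithm is testable without hardware.

## What it implements

* **Stage geometry** — the motor axes are rotated and scaled relative to
  the SEM image frame; displacements map through a 2×2 calibration matrix

  ```
  M = [  sx·cos(ax)   sx·sin(ax) ]
      [ -sy·sin(ay)   sy·cos(ay) ]
  ```

  estimated by least squares from displacement measurements
  (`estimate_calibration`), plus tile-grid layout with overlaps/gaps and
  adaptive (active/inactive) tile selection.
* **Debris detection and removal** — consecutive overview images compared
  by per-quadrant mean/SD differences (default), histogram total-variation
  distance, or changed-pixel fraction; on detection the sample is lowered
  70 nm and the knife sweeps the face, up to a configured maximum.
* **Focus control** — 512×384 through-focus series with sub-step parabolic
  refinement; a focus-gradient plane WD(x, y) = a·x + b·y + c fitted through
  three reference points to follow a tilted (knife-tilted) surface; and a
  continuous heuristic autofocus that estimates defocus from the width of
  the image autocorrelation's central peak and applies bounded corrections
  to already-acquired tiles (no extra dose).
* **Monitoring and inspection** — per-tile mean/SD deltas between
  consecutive slices, mandatory file-integrity checks, 512×384 previews,
  z-reslices and histograms.
* **The acquisition cycle** — overviews → debris loop → tiles (row-major,
  per-tile working distance, exactly-once even across pause/resume) →
  mirror sync → cut; three-attempt retry and a three-digit error-code
  taxonomy (1 communication, 2 microtome/stage, 3 SEM, 4 I/O,
  5 acquisition/inspection, 6 user).
* **Data handling** — uncompressed grayscale TIFFs under a parseable naming
  scheme, line-delimited metadata, checksum-verified mirror drive, and
  TrakEM2 image-list export. Electron dose per pixel is
  D = I·t / (e·A) with beam current I, dwell time t and pixel area A.

## Worked example

Using the bundled simulated-run configuration:

```
$ sbemctl estimate --config examples/demo.yaml
dose_e_per_nm2: 13.482 - 13.482
duration_s: 110.2
duration_h: 0.03
storage_bytes: 211440
storage_gib: 0.000
```

13.482 e⁻/nm² is the per-pixel electron dose of a 270 pA beam dwelling
0.8 µs on a 10 nm pixel; the duration estimate combines scan time with
stage-move and cut overheads, and storage is the exact byte count of all
scheduled 8-bit frames.

```
$ sbemctl calibrate --config examples/demo.yaml
angle_x_deg: 30.000000000
angle_y_deg: 28.000000000
scale_x: 1.020000000000
scale_y: 0.980000000000
```

The virtual stage only speaks motor coordinates; `calibrate` issues SEM
displacements, reads the motor readouts, and recovers the hidden axis
rotation/scaling exactly on the noise-free simulator.

```
$ sbemctl run --config examples/demo.yaml --slices 3
status=finished slices=3 debris_events=0
```

This writes 4 tiles + 1 overview per slice under `demo_out/` (e.g.
`tiles/g0000/t0000x0001/demo_g0000_t0000x0001_s00001.tif`), a tab-separated
statistics log, a main log, and `metadata.jsonl`, from which

```
$ sbemctl export-trakem2 --base-dir demo_out --out list.txt
tiles/g0000/t0000x0000/demo_g0000_t0000x0000_s00000.tif  0.0   0.0   0
tiles/g0000/t0000x0001/demo_g0000_t0000x0001_s00000.tif  56.0  0.0   0
...
```

exports tile positions in pixels (here the 56 px pitch of 64 px frames
with 8 px overlap) with the slice number as the section index, ready for
TrakEM2 stitching/alignment.

`sbemctl qc` runs the debris/monitoring checks offline over a directory of
TIFFs from a prior run, and `sbemctl simulate-phantom` renders the
phantom's noise-free ground truth for inspection.

## Layout

```
src/sbemctl/
  geometry.py     coordinate transforms, calibration, tile grids
  debris.py       the three detectors and the sweep loop
  focus.py        sharpness, through-focus, gradient, heuristic autofocus
  monitoring.py   tile stats, inspection, previews, reslices, histograms
  engine.py       the per-slice acquisition cycle, retries, estimates
  instrument.py   the virtual SBEM instrument
  protocol.py     trigger-file command exchange with the microtome host
  io_metadata.py  TIFF naming scheme, metadata, mirror, TrakEM2 export
  config.py       YAML run configurations and validation
  scenarios.py    canonical simulated study conditions
  cli.py          the `sbemctl` command
```

See `docs/methods.md` for the models, parameter choices, and limitations.
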