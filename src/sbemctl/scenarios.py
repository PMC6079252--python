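"""Canonical simulated-run scenarios.

These functions pin down the study conditions used to validate the control
algorithms on the virtual instrument — sample geometry, debris schedules,
fault schedules, calibration parameters — so the same conditions drive the
test suite, the acceptance script, and the documentation examples.
Problem sizes are desk-scale: small frames and tens of slices, enough to
exercise every control path.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .config import RunConfig, make_instrument
from .engine import AcquisitionEngine, BeamParams
from .errors import E_ACQUISITION_FAILURE, InstrumentFault
from .geometry import (OverviewSpec, StageCalibration, TileGrid,
                       estimate_calibration, sem_to_stage)
from .instrument import SemRect, SimulatorParams, VirtualInstrument
from .io_metadata import read_metadata

# The stage calibration used by every simulated scenario (a typical
# rotated/scaled motor-axis geometry).
SCENARIO_CALIBRATION = dict(angle_x=30.0, angle_y=28.0, scale_x=1.02, scale_y=0.98)

# Slices on which debris chunks land in the debris-pipeline scenario.
DEBRIS_SLICES = (7, 18, 26, 35, 44, 53, 62, 71, 85, 93)
# A medium-size chunk: 8 x 6 um, 60 gray levels, lying inside one quadrant
# of the 30 x 22.5 um overview.
DEBRIS_PATCH = SemRect(-11.0, -8.0, 8.0, 6.0)
DEBRIS_CONTRAST = 60.0


def scenario_calibration() -> StageCalibration:
    return StageCalibration(**SCENARIO_CALIBRATION)


def base_config(base_dir: Path, seed: int, *, n_slices: int = 5,
                grids: Optional[List[TileGrid]] = None,
                overviews: Optional[List[OverviewSpec]] = None,
                **overrides) -> RunConfig:
    """A small but complete simulated run configuration."""
    if grids is None:
        grids = [TileGrid(0, (-8.0, -6.0), 2, 2, (64, 48), 10.0, overlap=8,
                          dwell_time=0.8)]
    if overviews is None:
        overviews = [OverviewSpec(0, (0.0, 0.0), (200, 150), 150.0)]
    cfg = RunConfig(
        stack_name="sim",
        base_dir=str(base_dir),
        calibration=scenario_calibration(),
        grids=grids,
        overviews=overviews,
        beam=BeamParams(current=270.0, dwell_time=0.8, pixel_size=10.0),
        number_of_slices=n_slices,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def run_debris_scenario(base_dir: Path, seed: int, n_slices: int = 100
                        ) -> Tuple[AcquisitionEngine, VirtualInstrument]:
    """100-slice overview-only run with removable debris chunks on ten
    known slices, default quadrant detection thresholds."""
    cfg = base_config(base_dir, seed, n_slices=n_slices, grids=[])
    inst = make_instrument(cfg)
    for s in DEBRIS_SLICES:
        if s < n_slices:
            inst.inject_debris(s, DEBRIS_PATCH, DEBRIS_CONTRAST,
                               removal_probability=1.0)
    engine = AcquisitionEngine(cfg, inst)
    engine.run()
    return engine, inst


def read_debris_log(base_dir: Path) -> List[Tuple[int, int, str, float, float, int]]:
    """Parsed debris event log: (slice, ov, method, max_diff, threshold, sweeps)."""
    path = Path(base_dir) / "debris.log"
    if not path.exists():
        return []
    out = []
    for line in path.read_text().splitlines():
        s, ov, method, md, th, sw = line.split("\t")
        out.append((int(s), int(ov), method, float(md), float(th), int(sw)))
    return out


def recover_calibration(seed: int = 0) -> Tuple[StageCalibration, StageCalibration]:
    """(hidden, recovered) calibration from simulated displacement
    measurements — the `calibrate` procedure."""
    hidden = scenario_calibration()
    inst = VirtualInstrument(SimulatorParams(), hidden, seed=seed)
    displacements = [(20.0, 0.0), (0.0, 20.0), (15.0, 15.0), (-10.0, 25.0)]
    pairs = [(d, inst.measure_motor_displacement(d)) for d in displacements]
    return hidden, estimate_calibration(pairs)


def recover_focus_gradient(seed: int = 0, wd_step: float = 0.001,
                           n_frames: int = 9) -> Dict[str, float]:
    """Measure the knife tilt with through-focus series at three corners
    and predict the working distance at the fourth."""
    from .focus import (fit_focus_gradient, interpolate_best_index,
                        sharpness_score, through_focus_series)

    cal = scenario_calibration()
    inst = VirtualInstrument(SimulatorParams(), cal, seed=seed)

    def best_wd(pos):
        def acquire(wd, frame):
            return inst.acquire_frame(sem_to_stage(pos, cal), frame, 10.0, 4.0, wd)
        frames, idx = through_focus_series(acquire, inst.params.base_wd,
                                           wd_step, n_frames)
        k = interpolate_best_index([sharpness_score(f) for f in frames], idx)
        return inst.params.base_wd + (k - (n_frames - 1) // 2) * wd_step

    pts = [(-40.0, -30.0), (40.0, -30.0), (-40.0, 30.0)]
    gradient = fit_focus_gradient([(p, best_wd(p)) for p in pts])
    p4 = (40.0, 30.0)
    return {
        "predicted_wd": gradient.wd_at(p4),
        "true_wd": inst.true_wd(p4),
        "error_mm": abs(gradient.wd_at(p4) - inst.true_wd(p4)),
        "wd_step": wd_step,
        "tilt_a": gradient.a,
        "tilt_b": gradient.b,
    }


class FaultyBackend:
    """Backend wrapper that fails three consecutive acquisition attempts
    starting at the n-th acquire call (a scripted fault schedule)."""

    def __init__(self, instrument: VirtualInstrument, fail_at: int,
                 n_failures: int = 3):
        self._inst = instrument
        self.calls = 0
        self.fail_at = fail_at
        self.remaining = n_failures

    def __getattr__(self, name):
        return getattr(self._inst, name)

    def acquire_frame(self, *args, **kwargs):
        self.calls += 1
        if self.calls >= self.fail_at and self.remaining > 0:
            self.remaining -= 1
            raise InstrumentFault(E_ACQUISITION_FAILURE, "scheduled fault")
        return self._inst.acquire_frame(*args, **kwargs)


def run_with_fault_schedule(base_dir: Path, seed: int, fail_at: int,
                            n_slices: int = 3) -> AcquisitionEngine:
    """Run a small grid acquisition with a fault injected at acquire call
    ``fail_at``, resuming after every pause until the stack finishes."""
    cfg = base_config(base_dir, seed, n_slices=n_slices,
                      overviews=[OverviewSpec(0, (0.0, 0.0), (120, 90), 150.0)])
    inst = make_instrument(cfg)
    engine = AcquisitionEngine(cfg, FaultyBackend(inst, fail_at))
    for _ in range(20):  # resume after pauses; a schedule pauses at most a few times
        engine.run()
        if engine.state.status == "finished":
            break
        engine.resume()
    return engine


def tile_write_counts(base_dir: Path) -> Dict[Tuple[int, int, int, int], int]:
    """(slice, grid, row, col) -> number of metadata records (file writes)."""
    counts: Dict[Tuple[int, int, int, int], int] = {}
    for rec in read_metadata(base_dir):
        if rec.grid_id < 0:
            continue
        key = (rec.slice_idx, rec.grid_id, rec.row, rec.col)
        counts[key] = counts.get(key, 0) + 1
    return counts


def image_tree_checksums(base_dir: Path) -> Dict[str, str]:
    """sha256 of every image file, keyed by path relative to base_dir."""
    out = {}
    for p in sorted(Path(base_dir).rglob("*.tif")):
        out[str(p.relative_to(base_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_determinism_pair(dir_a: Path, dir_b: Path, seed: int,
                         n_slices: int = 5) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Two identical full simulated runs; returns both checksum trees."""
    trees = []
    for d in (dir_a, dir_b):
        cfg = base_config(Path(d), seed, n_slices=n_slices)
        inst = make_instrument(cfg)
        AcquisitionEngine(cfg, inst).run()
        trees.append(image_tree_checksums(Path(d)))
    return trees[0], trees[1]
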