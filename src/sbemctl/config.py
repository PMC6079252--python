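"""Run configuration files.

All system settings, calibrations and acquisition parameters live in one
YAML file per user/project, so several users can share a system while each
keeps their own configuration.  Loading applies documented defaults (sweep
depth 70 nm, stub mosaic pixel size 372 nm, 3 retry attempts, 0.1 s
protocol poll interval) and validates every invariant before any
instrument command is issued; a config with violations refuses to start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Set, Tuple

import numpy as np
import yaml

from .debris import DEFAULT_SWEEP_DEPTH_NM, METHODS, SweepPolicy
from .engine import BeamParams, DEFAULT_RETRY_ATTEMPTS
from .errors import E_CONFIG, SbemError
from .geometry import (OverviewSpec, Rect, StageCalibration, StubOverviewSpec,
                       TileGrid)
from .instrument import SimulatorParams, VirtualInstrument
from .protocol import POLL_INTERVAL_S


@dataclass
class RunConfig:
    """Validated, fully-defaulted acquisition run description."""

    stack_name: str
    base_dir: str
    calibration: StageCalibration
    grids: List[TileGrid]
    overviews: List[OverviewSpec]
    beam: BeamParams
    number_of_slices: int
    seed: int
    mirror_dir: Optional[str] = None
    stub: StubOverviewSpec = field(default_factory=StubOverviewSpec)
    sweep_policy: SweepPolicy = field(default_factory=SweepPolicy)
    slice_thickness: float = 25.0  # nm
    wd: float = 7.0  # mm, global working distance
    # debris detection
    debris_method: str = "quadrant_meansd"
    debris_mean_threshold: float = 10.0
    debris_sd_threshold: float = 10.0
    debris_tv_threshold: float = 0.10
    debris_pixel_delta: float = 25.0
    debris_fraction_threshold: float = 0.05
    restrict_detection_to_active: bool = False
    # monitoring / inspection
    monitor_mean_threshold: float = 20.0
    monitor_sd_threshold: float = 15.0
    monitor_range_limits: Tuple[float, float, float, float] = (1.0, 254.0, 0.0, 255.0)
    user_predicate: Optional[Callable[[np.ndarray], bool]] = None
    # autofocus
    autofocus_mode: str = "none"  # none | heuristic | periodic
    autofocus_interval: int = 25
    autofocus_offset: int = 0
    autofocus_gain: float = 5e-4
    autofocus_max_step: float = 0.002  # mm
    autofocus_wd_step: float = 0.001  # mm, through-focus step
    autofocus_n_frames: int = 9
    autofocus_ref_tiles: Set[Tuple[int, int]] = field(default_factory=set)
    # engine constants
    retry_attempts: int = DEFAULT_RETRY_ATTEMPTS
    poll_interval: float = POLL_INTERVAL_S
    stage_move_overhead_s: float = 2.0
    cut_overhead_s: float = 12.0
    bytes_per_pixel: int = 1
    # simulator
    simulator: SimulatorParams = field(default_factory=SimulatorParams)


def validate(config: RunConfig) -> List[str]:
    """Cross-field invariant checks; returns human-readable violations
    with field paths."""
    v: List[str] = []
    if config.number_of_slices < 1:
        v.append("number_of_slices: must be >= 1")
    if config.slice_thickness <= 0:
        v.append("slice_thickness: must be > 0 nm")
    if config.debris_method not in METHODS:
        v.append(f"debris_method: unknown method {config.debris_method!r}")
    if config.autofocus_mode not in ("none", "heuristic", "periodic"):
        v.append(f"autofocus_mode: unknown mode {config.autofocus_mode!r}")
    if config.autofocus_interval < 1:
        v.append("autofocus_interval: must be >= 1")
    if config.retry_attempts < 1:
        v.append("retry_attempts: must be >= 1")
    for i, g in enumerate(config.grids):
        if g.overlap >= min(g.frame_size):
            v.append(f"grids[{i}] (grid {g.grid_id}): overlap {g.overlap} px >= "
                     f"frame dimension {min(g.frame_size)} px")
        if not 0 <= g.interval_offset < g.acquisition_interval:
            v.append(f"grids[{i}]: interval_offset must be in [0, interval)")
    for i, ov in enumerate(config.overviews):
        if not 0 <= ov.interval_offset < ov.acquisition_interval:
            v.append(f"overviews[{i}]: interval_offset must be in [0, interval)")
    mn, mx, sn, sx = config.monitor_range_limits
    if mn > mx or sn > sx:
        v.append("monitor_range_limits: min exceeds max")
    return v


def _build(d: dict, path: Path) -> RunConfig:
    def req(key: str):
        if key not in d:
            raise SbemError(E_CONFIG, f"{key}: required field missing")
        return d[key]

    cal = req("calibration")
    calibration = StageCalibration(
        angle_x=float(cal["angle_x_deg"]), angle_y=float(cal["angle_y_deg"]),
        scale_x=float(cal["scale_x"]), scale_y=float(cal["scale_y"]))

    grids = []
    for g in d.get("grids", []):
        active = g.get("active", "all")
        grids.append(TileGrid(
            grid_id=int(g["grid_id"]),
            origin_sem=tuple(g["origin_sem_um"]),
            rows=int(g["rows"]), cols=int(g["cols"]),
            frame_size=tuple(g["frame_size_px"]),
            pixel_size=float(g["pixel_size_nm"]),
            overlap=int(g.get("overlap_px", 0)),
            dwell_time=float(g.get("dwell_time_us", d.get("beam", {}).get("dwell_time_us", 0.8))),
            active=None if active == "all" else {tuple(t) for t in active},
            acquisition_interval=int(g.get("acquisition_interval", 1)),
            interval_offset=int(g.get("interval_offset", 0)),
            wd_override={tuple(map(int, k.split(","))): float(v)
                         for k, v in g.get("wd_override", {}).items()},
        ))

    overviews = []
    for o in d.get("overviews", []):
        det = o.get("detection_region")
        overviews.append(OverviewSpec(
            ov_id=int(o["ov_id"]),
            center_sem=tuple(o["center_sem_um"]),
            frame_size=tuple(o["frame_size_px"]),
            pixel_size=float(o["pixel_size_nm"]),
            acquisition_interval=int(o.get("acquisition_interval", 1)),
            interval_offset=int(o.get("interval_offset", 0)),
            detection_region=None if det is None else Rect(*det),
            dwell_time=float(o.get("dwell_time_us", 0.8)),
        ))

    b = req("beam")
    beam = BeamParams(current=float(b["current_pa"]),
                      dwell_time=float(b["dwell_time_us"]),
                      pixel_size=float(b.get("pixel_size_nm",
                                             grids[0].pixel_size if grids else 10.0)),
                      landing_energy=float(b.get("landing_energy_kev", 1.8)))

    stub_d = d.get("stub", {})
    stub = StubOverviewSpec(
        center_sem=tuple(stub_d.get("center_sem_um", (0.0, 0.0))),
        size=tuple(stub_d.get("size_um", (400.0, 300.0))),
        pixel_size=float(stub_d.get("pixel_size_nm", StubOverviewSpec.pixel_size)))

    sp = d.get("sweep_policy", {})
    sweep_policy = SweepPolicy(
        depth=float(sp.get("depth_nm", DEFAULT_SWEEP_DEPTH_NM)),
        max_sweeps=int(sp.get("max_sweeps", 3)),
        continue_after_max=bool(sp.get("continue_after_max", False)))

    deb = d.get("debris", {})
    mon = d.get("monitoring", {})
    af = d.get("autofocus", {})
    sim_d = d.get("simulator", {})
    sim_kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in sim_d.items()}
    simulator = SimulatorParams(**sim_kwargs)

    base_dir = str(req("base_dir"))
    if not Path(base_dir).is_absolute():
        base_dir = str((path.parent / base_dir).resolve())
    mirror_dir = d.get("mirror_dir")
    if mirror_dir is not None and not Path(mirror_dir).is_absolute():
        mirror_dir = str((path.parent / mirror_dir).resolve())

    return RunConfig(
        stack_name=str(req("stack_name")),
        base_dir=base_dir,
        mirror_dir=mirror_dir,
        calibration=calibration,
        grids=grids,
        overviews=overviews,
        beam=beam,
        stub=stub,
        sweep_policy=sweep_policy,
        number_of_slices=int(req("number_of_slices")),
        seed=int(req("seed")),
        slice_thickness=float(d.get("slice_thickness_nm", 25.0)),
        wd=float(d.get("working_distance_mm", simulator.base_wd)),
        debris_method=str(deb.get("method", "quadrant_meansd")),
        debris_mean_threshold=float(deb.get("mean_threshold", 10.0)),
        debris_sd_threshold=float(deb.get("sd_threshold", 10.0)),
        debris_tv_threshold=float(deb.get("tv_threshold", 0.10)),
        debris_pixel_delta=float(deb.get("pixel_delta", 25.0)),
        debris_fraction_threshold=float(deb.get("fraction_threshold", 0.05)),
        restrict_detection_to_active=bool(deb.get("restrict_to_active", False)),
        monitor_mean_threshold=float(mon.get("mean_threshold", 20.0)),
        monitor_sd_threshold=float(mon.get("sd_threshold", 15.0)),
        monitor_range_limits=tuple(mon.get("range_limits", (1.0, 254.0, 0.0, 255.0))),
        autofocus_mode=str(af.get("mode", "none")),
        autofocus_interval=int(af.get("interval", 25)),
        autofocus_offset=int(af.get("offset", 0)),
        autofocus_gain=float(af.get("gain", 5e-4)),
        autofocus_max_step=float(af.get("max_step_mm", 0.002)),
        autofocus_wd_step=float(af.get("wd_step_mm", 0.001)),
        autofocus_n_frames=int(af.get("n_frames", 9)),
        autofocus_ref_tiles={tuple(t) for t in af.get("ref_tiles", [])},
        retry_attempts=int(d.get("retry_attempts", DEFAULT_RETRY_ATTEMPTS)),
        poll_interval=float(d.get("poll_interval_s", POLL_INTERVAL_S)),
        stage_move_overhead_s=float(d.get("stage_move_overhead_s", 2.0)),
        cut_overhead_s=float(d.get("cut_overhead_s", 12.0)),
        bytes_per_pixel=int(d.get("bytes_per_pixel", 1)),
        simulator=simulator,
    )


def load_config(path) -> RunConfig:
    """Parse, default-fill, and validate a run configuration.

    Raises a group-5 configuration error listing every violation; a config
    that fails to validate never starts a run.
    """
    path = Path(path)
    if not path.exists():
        raise SbemError(E_CONFIG, f"config file not found: {path}")
    try:
        d = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise SbemError(E_CONFIG, f"cannot parse {path}: {exc}") from exc
    config = _build(d, path)
    violations = validate(config)
    if violations:
        raise SbemError(E_CONFIG, "; ".join(violations))
    return config


def config_to_dict(config: RunConfig) -> dict:
    """Serializable form of a config (inverse of loading)."""
    c = config
    return {
        "stack_name": c.stack_name,
        "base_dir": c.base_dir,
        "mirror_dir": c.mirror_dir,
        "number_of_slices": c.number_of_slices,
        "seed": c.seed,
        "slice_thickness_nm": c.slice_thickness,
        "working_distance_mm": c.wd,
        "retry_attempts": c.retry_attempts,
        "poll_interval_s": c.poll_interval,
        "stage_move_overhead_s": c.stage_move_overhead_s,
        "cut_overhead_s": c.cut_overhead_s,
        "bytes_per_pixel": c.bytes_per_pixel,
        "calibration": {"angle_x_deg": c.calibration.angle_x,
                        "angle_y_deg": c.calibration.angle_y,
                        "scale_x": c.calibration.scale_x,
                        "scale_y": c.calibration.scale_y},
        "beam": {"current_pa": c.beam.current, "dwell_time_us": c.beam.dwell_time,
                 "pixel_size_nm": c.beam.pixel_size,
                 "landing_energy_kev": c.beam.landing_energy},
        "grids": [{
            "grid_id": g.grid_id, "origin_sem_um": list(g.origin_sem),
            "rows": g.rows, "cols": g.cols, "frame_size_px": list(g.frame_size),
            "pixel_size_nm": g.pixel_size, "overlap_px": g.overlap,
            "dwell_time_us": g.dwell_time,
            "active": sorted([list(t) for t in g.active]),
            "acquisition_interval": g.acquisition_interval,
            "interval_offset": g.interval_offset,
            "wd_override": {f"{r},{cc}": wd for (r, cc), wd in g.wd_override.items()},
        } for g in c.grids],
        "overviews": [{
            "ov_id": o.ov_id, "center_sem_um": list(o.center_sem),
            "frame_size_px": list(o.frame_size), "pixel_size_nm": o.pixel_size,
            "acquisition_interval": o.acquisition_interval,
            "interval_offset": o.interval_offset,
            "detection_region": [o.detection_region.x, o.detection_region.y,
                                 o.detection_region.w, o.detection_region.h],
            "dwell_time_us": o.dwell_time,
        } for o in c.overviews],
        "stub": {"center_sem_um": list(c.stub.center_sem),
                 "size_um": list(c.stub.size), "pixel_size_nm": c.stub.pixel_size},
        "sweep_policy": {"depth_nm": c.sweep_policy.depth,
                         "max_sweeps": c.sweep_policy.max_sweeps,
                         "continue_after_max": c.sweep_policy.continue_after_max},
        "debris": {"method": c.debris_method,
                   "mean_threshold": c.debris_mean_threshold,
                   "sd_threshold": c.debris_sd_threshold,
                   "tv_threshold": c.debris_tv_threshold,
                   "pixel_delta": c.debris_pixel_delta,
                   "fraction_threshold": c.debris_fraction_threshold,
                   "restrict_to_active": c.restrict_detection_to_active},
        "monitoring": {"mean_threshold": c.monitor_mean_threshold,
                       "sd_threshold": c.monitor_sd_threshold,
                       "range_limits": list(c.monitor_range_limits)},
        "autofocus": {"mode": c.autofocus_mode, "interval": c.autofocus_interval,
                      "offset": c.autofocus_offset, "gain": c.autofocus_gain,
                      "max_step_mm": c.autofocus_max_step,
                      "wd_step_mm": c.autofocus_wd_step,
                      "n_frames": c.autofocus_n_frames,
                      "ref_tiles": sorted([list(t) for t in c.autofocus_ref_tiles])},
        "simulator": {
            "base_wd": c.simulator.base_wd,
            "knife_tilt": list(c.simulator.knife_tilt),
            "wd_drift_per_slice": c.simulator.wd_drift_per_slice,
            "blur_nm_per_mm": c.simulator.blur_nm_per_mm,
            "noise_scale": c.simulator.noise_scale,
            "texture_contrast": c.simulator.texture_contrast,
            "specimen_center": list(c.simulator.specimen_center),
            "specimen_semiaxes": list(c.simulator.specimen_semiaxes),
            "specimen_brightness": c.simulator.specimen_brightness,
            "motor_range_um": c.simulator.motor_range_um,
            "autofocus_residual_mm": c.simulator.autofocus_residual_mm,
        },
    }


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def make_instrument(config: RunConfig, seed: Optional[int] = None) -> VirtualInstrument:
    """Build the virtual instrument for a simulated run.  The instrument's
    hidden stage calibration equals the configured one (a previously
    calibrated system)."""
    return VirtualInstrument(params=config.simulator,
                             calibration=config.calibration,
                             seed=config.seed if seed is None else seed)
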