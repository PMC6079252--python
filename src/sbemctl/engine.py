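"""The per-slice acquisition cycle.

Each cycle: (1) acquire the overviews due on this slice; (2) run the debris
detection/sweep loop on each; (3) acquire all remaining active tiles of the
grids due on this slice, in row-major order, with per-tile working
distance, preview generation, inspection, and statistics monitoring;
(4) sync the mirror drive; (5) cut one slice; (6) advance the slice
counter.  Failed operations are retried (three attempts total by default);
a persistent failure or a failed check pauses the acquisition with a
three-digit error code, keeping the set of already-acquired tiles so the
run resumes at the correct position in the grid and no tile is ever
scanned twice.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Set, Tuple

import numpy as np

from . import debris as debris_mod
from . import focus as focus_mod
from . import monitoring
from .errors import (E_DEBRIS_UNRESOLVED, E_RANGE_VIOLATION, E_TILE_DELTA,
                     E_UNIFORM_IMAGE, InstrumentFault, SbemError)
from .geometry import (EmptyRegionError, OverviewSpec, Rect, TileGrid,
                       active_bounding_region, sem_to_stage)
from .io_metadata import (TileRecord, mirror_sync, overview_relpath,
                          tile_relpath, write_tile)

ELEMENTARY_CHARGE_C = 1.602176634e-19

# Sentinel file checked once per cycle; stands in for remote pause commands.
PAUSE_SENTINEL = "pause.cmd"

DEFAULT_RETRY_ATTEMPTS = 3


@dataclass
class BeamParams:
    """Electron-beam settings that determine dose and imaging time."""

    current: float  # pA
    dwell_time: float  # us
    pixel_size: float  # nm (per-pixel area A = pixel_size**2)
    landing_energy: float = 1.8  # keV, carried as metadata

    def __post_init__(self) -> None:
        if self.current <= 0 or self.dwell_time <= 0 or self.pixel_size <= 0:
            raise ValueError("beam current, dwell time and pixel size must be > 0")


def electron_dose(beam: BeamParams) -> float:
    """Electron dose in electrons per nm^2: (I*t) / (e*A)."""
    i_amp = beam.current * 1e-12
    t_s = beam.dwell_time * 1e-6
    area_nm2 = beam.pixel_size ** 2
    return i_amp * t_s / (ELEMENTARY_CHARGE_C * area_nm2)


def dose_range(beam: BeamParams, grids: List[TileGrid]) -> Tuple[float, float]:
    """Min-max dose over all configured grids (each grid may override the
    dwell time and pixel size)."""
    doses = [electron_dose(BeamParams(beam.current, g.dwell_time, g.pixel_size,
                                      beam.landing_energy))
             for g in grids] or [electron_dose(beam)]
    return (min(doses), max(doses))


def schedule_due(slice_idx: int, interval: int, offset: int = 0) -> bool:
    """True when an item with the given acquisition interval/offset is due
    on this slice (e.g. interval 10 = a mosaic on every tenth slice)."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if not 0 <= offset < interval:
        raise ValueError("offset must satisfy 0 <= offset < interval")
    return (slice_idx - offset) % interval == 0


def with_retry(action: Callable[[], object], max_attempts: int = DEFAULT_RETRY_ATTEMPTS,
               log: Optional[Callable[[str], None]] = None):
    """Run an idempotent instrument action with retries.

    Up to ``max_attempts`` total attempts; each failure logs a warning and
    the final failure re-raises the mapped error.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    last: Optional[SbemError] = None
    for attempt in range(1, max_attempts + 1):
        try:
            return action()
        except InstrumentFault as exc:
            last = exc
            if log is not None:
                log(f"WARNING attempt {attempt}/{max_attempts} failed: {exc}")
    assert last is not None
    raise last


def estimate_duration_storage(config) -> Tuple[float, int]:
    """Predicted acquisition duration (s) and dataset size (bytes).

    duration = sum of per-frame scan times (pixels * dwell) plus a per-tile
    stage-move overhead and a per-slice cut overhead; storage = total
    pixels at the configured bit depth.  Both change as active-tile sets
    change.
    """
    seconds = 0.0
    nbytes = 0
    bpp = config.bytes_per_pixel
    for s in range(config.number_of_slices):
        for grid in config.grids:
            if not schedule_due(s, grid.acquisition_interval, grid.interval_offset):
                continue
            w, h = grid.frame_size
            n = len(grid.active)
            seconds += n * (w * h * grid.dwell_time * 1e-6 + config.stage_move_overhead_s)
            nbytes += n * w * h * bpp
        for ov in config.overviews:
            if not schedule_due(s, ov.acquisition_interval, ov.interval_offset):
                continue
            w, h = ov.frame_size
            seconds += w * h * ov.dwell_time * 1e-6 + config.stage_move_overhead_s
            nbytes += w * h * bpp
        seconds += config.cut_overhead_s
    return seconds, nbytes


@dataclass
class AcquisitionState:
    """Mutable run state; survives pause/resume."""

    slice_idx: int = 0
    acquired_tiles: Set[Tuple[int, int, int]] = field(default_factory=set)
    acquired_overviews: Set[int] = field(default_factory=set)
    status: str = "running"  # running | paused | finished
    pause_reason: str = ""
    error_code: Optional[int] = None
    slice_thickness: float = 25.0  # nm


class AcquisitionEngine:
    """Drives a stack acquisition against an instrument backend."""

    def __init__(self, config, instrument, base_dir: Optional[Path] = None):
        self.config = config
        self.instrument = instrument
        self.base_dir = Path(base_dir or config.base_dir)
        self.base_dir.mkdir(parents=True, exist_ok=True)
        self.state = AcquisitionState(slice_thickness=config.slice_thickness)
        self.focus_state = focus_mod.FocusState(wd=config.wd)
        self.references: Dict[int, np.ndarray] = {}  # ov_id -> last clean overview
        self.last_stats: Dict[Tuple[int, int, int], monitoring.TileStats] = {}
        self.previews: Dict[Tuple[int, int, int], np.ndarray] = {}
        self._pending_mirror: List[str] = []
        self.debris_events = 0

    # ------------------------------------------------------------- logging

    def _stamp(self) -> str:
        return datetime.datetime.now().strftime("%Y-%m-%d %H:%M:%S")

    def log(self, msg: str) -> None:
        with open(self.base_dir / "main.log", "a") as fh:
            fh.write(f"{self._stamp()} {msg}\n")

    def notify(self, msg: str) -> None:
        self.log(f"NOTIFY {msg}")
        with open(self.base_dir / "notifications.log", "a") as fh:
            fh.write(f"{self._stamp()} {msg}\n")

    def _log_debris_event(self, ov_id: int, report, sweeps: int) -> None:
        self.debris_events += 1
        with open(self.base_dir / "debris.log", "a") as fh:
            fh.write(f"{self.state.slice_idx}\t{ov_id}\t{report.method}\t"
                     f"{report.max_diff:.4f}\t{report.threshold:.4f}\t{sweeps}\n")

    def _log_stats(self, st: monitoring.TileStats) -> None:
        with open(self.base_dir / "stats.tsv", "a") as fh:
            fh.write(f"{st.slice_idx}\t{st.grid_id}\t{st.row}\t{st.col}\t"
                     f"{st.mean:.4f}\t{st.sd:.4f}\n")

    def _pause(self, code: int, reason: str) -> None:
        self.state.status = "paused"
        self.state.pause_reason = reason
        self.state.error_code = code
        self.notify(f"PAUSED E{code}: {reason}")

    def resume(self) -> None:
        """Clear the pause condition; the next :meth:`run` call continues at
        the correct position in the grid."""
        if self.state.status == "paused":
            self.state.status = "running"
            self.state.pause_reason = ""
            self.state.error_code = None
            self.log("resumed")

    # ------------------------------------------------------------- helpers

    def _motor(self, sem_pos) -> Tuple[float, float]:
        return sem_to_stage(sem_pos, self.config.calibration)

    def _detect(self, prev: np.ndarray, curr: np.ndarray, region: Rect):
        c = self.config
        if c.debris_method == "quadrant_meansd":
            return debris_mod.detect_debris_quadrant(
                prev, curr, region, c.debris_mean_threshold, c.debris_sd_threshold)
        if c.debris_method == "histogram":
            return debris_mod.detect_debris_histogram(prev, curr, region,
                                                      c.debris_tv_threshold)
        return debris_mod.detect_debris_pixel(prev, curr, region,
                                              c.debris_pixel_delta,
                                              c.debris_fraction_threshold)

    def _detection_region(self, ov: OverviewSpec) -> Rect:
        if not self.config.restrict_detection_to_active:
            return ov.detection_region
        rects = []
        for grid in self.config.grids:
            try:
                rects.append(active_bounding_region(grid, ov))
            except EmptyRegionError:
                continue
        if not rects:
            return ov.detection_region
        x0 = min(r.x for r in rects)
        y0 = min(r.y for r in rects)
        x1 = max(r.x + r.w for r in rects)
        y1 = max(r.y + r.h for r in rects)
        return Rect(x0, y0, x1 - x0, y1 - y0).clip(*ov.frame_size)

    def _acquire_overview(self, ov: OverviewSpec) -> np.ndarray:
        return with_retry(
            lambda: self.instrument.acquire_frame(
                self._motor(ov.center_sem), ov.frame_size, ov.pixel_size,
                ov.dwell_time, self.focus_state.wd),
            self.config.retry_attempts, self.log)

    # ---------------------------------------------------------- slice cycle

    def run_slice(self) -> AcquisitionState:
        """Execute one full acquisition cycle (one slice)."""
        st = self.state
        if st.status != "running":
            raise SbemError(E_RANGE_VIOLATION, f"cannot run in status {st.status}")
        if (self.base_dir / PAUSE_SENTINEL).exists():
            self._pause(601, "remote pause command file present")
            return st
        s = st.slice_idx
        self.log(f"slice {s} begin")
        try:
            # (1)+(2) overviews with the debris loop
            for ov in self.config.overviews:
                if not schedule_due(s, ov.acquisition_interval, ov.interval_offset):
                    continue
                if ov.ov_id in st.acquired_overviews:
                    continue  # done before a pause on this slice
                if not self._overview_cycle(ov):
                    return st
            # periodic (vendor) autofocus on reference tiles
            self._periodic_autofocus()
            # (3) tiles of all due grids
            for grid in sorted(self.config.grids, key=lambda g: g.grid_id):
                if not schedule_due(s, grid.acquisition_interval, grid.interval_offset):
                    continue
                if not self._acquire_grid(grid):
                    return st
            # (4) mirror
            self._mirror()
            # (5) cut
            with_retry(lambda: self.instrument.cut(st.slice_thickness),
                       self.config.retry_attempts, self.log)
        except SbemError as exc:
            self._pause(exc.code, exc.error.message)
            return st
        # (6) advance
        st.slice_idx += 1
        st.acquired_tiles.clear()
        st.acquired_overviews.clear()
        self.log(f"slice {s} done")
        return st

    def _overview_cycle(self, ov: OverviewSpec) -> bool:
        """Acquire one overview, run the debris loop, persist the accepted
        image.  Returns False when the run paused."""
        img = self._acquire_overview(ov)
        if ov.ov_id not in self.references:
            # The very first overview is confirmed debris-free by the user
            # (here: by configuration) and seeds the clean reference.
            self.references[ov.ov_id] = img
            self._write_overview(ov, img)
            self.state.acquired_overviews.add(ov.ov_id)
            return True
        region = self._detection_region(ov)
        policy = self.config.sweep_policy
        sweep_fn = lambda depth: with_retry(  # noqa: E731
            lambda: self.instrument.sweep(depth), self.config.retry_attempts, self.log)
        outcome = debris_mod.sweep_until_clean(
            acquire_overview=lambda: self._acquire_overview(ov),
            sweep=sweep_fn,
            reference=self.references[ov.ov_id],
            first_image=img,
            detect=lambda prev, curr: self._detect(prev, curr, region),
            policy=policy,
            log=self.log)
        if outcome.sweeps > 0 or outcome.status != "clean":
            self._log_debris_event(ov.ov_id, outcome.reports[0], outcome.sweeps)
        self._write_overview(ov, outcome.final_image)
        if outcome.status == "clean":
            self.references[ov.ov_id] = outcome.final_image
            self.state.acquired_overviews.add(ov.ov_id)
            return True
        if outcome.status == "continued_with_debris":
            self.log(f"continuing with debris on overview {ov.ov_id}")
            self.state.acquired_overviews.add(ov.ov_id)
            return True
        self._pause(E_DEBRIS_UNRESOLVED,
                    f"debris on overview {ov.ov_id} not removed after "
                    f"{outcome.sweeps} sweeps")
        return False

    def _write_overview(self, ov: OverviewSpec, img: np.ndarray) -> None:
        rel = overview_relpath(self.config.stack_name, ov.ov_id, self.state.slice_idx)
        rec = TileRecord(path=rel, grid_id=-1, row=ov.ov_id, col=0,
                         slice_idx=self.state.slice_idx,
                         stage_pos=self._motor(ov.center_sem),
                         sem_pos=tuple(ov.center_sem), pixel_size=ov.pixel_size,
                         wd=self.focus_state.wd)
        write_tile(img, rec, self.base_dir)
        self._pending_mirror.append(rel)

    def _periodic_autofocus(self) -> None:
        c = self.config
        if c.autofocus_mode != "periodic" or not c.grids:
            return
        due = focus_mod.periodic_autofocus_due(
            self.state.slice_idx, c.autofocus_interval, c.autofocus_ref_tiles,
            c.autofocus_offset)
        grid = c.grids[0]
        for (r, col) in sorted(due):
            wd = self.instrument.vendor_autofocus(self._motor(grid.tile_center(r, col)))
            self.focus_state.wd = wd
            self.log(f"periodic autofocus at tile ({r},{col}): wd={wd:.6f} mm")

    def _acquire_grid(self, grid: TileGrid) -> bool:
        c = self.config
        st = self.state
        for (row, col) in grid.active_sorted():
            key = (grid.grid_id, row, col)
            if key in st.acquired_tiles:
                continue  # already done before a pause on this slice
            wd = focus_mod.wd_for_tile(grid, row, col, self.focus_state.wd)
            center = grid.tile_center(row, col)
            img = with_retry(
                lambda: self.instrument.acquire_frame(
                    self._motor(center), grid.frame_size, grid.pixel_size,
                    grid.dwell_time, wd),
                c.retry_attempts, self.log)
            rel = tile_relpath(c.stack_name, grid.grid_id, row, col, st.slice_idx)
            rec = TileRecord(path=rel, grid_id=grid.grid_id, row=row, col=col,
                             slice_idx=st.slice_idx, stage_pos=self._motor(center),
                             sem_pos=center, pixel_size=grid.pixel_size, wd=wd)
            path = write_tile(img, rec, self.base_dir)
            self.previews[key] = monitoring.make_preview(img, warn=self.log)
            result = monitoring.inspect_image(
                path, grid.frame_size, c.monitor_range_limits,
                user_predicate=c.user_predicate)
            if not result.accepted:
                self._pause(E_UNIFORM_IMAGE,
                            f"inspection failed on tile {key} slice {st.slice_idx}: "
                            f"{result.failed()}")
                return False
            if result.action == "discard":
                self.log(f"discard tile {key} slice {st.slice_idx} (user predicate)")
                path.unlink()
            else:
                self._pending_mirror.append(rel)
            stats = monitoring.compute_stats(img, st.slice_idx, grid.grid_id, row, col)
            self._log_stats(stats)
            st.acquired_tiles.add(key)
            prev = self.last_stats.get(key)
            self.last_stats[key] = stats
            if prev is not None and monitoring.tile_delta_check(
                    prev, stats, c.monitor_mean_threshold,
                    c.monitor_sd_threshold) == "pause":
                self._pause(E_TILE_DELTA,
                            f"tile {key} stats jumped on slice {st.slice_idx} "
                            f"(mean {prev.mean:.1f}->{stats.mean:.1f}, "
                            f"sd {prev.sd:.1f}->{stats.sd:.1f})")
                return False
            if c.autofocus_mode == "heuristic":
                focus_mod.heuristic_autofocus_update(
                    img, self.focus_state, c.autofocus_gain, c.autofocus_max_step)
        return True

    def _mirror(self) -> None:
        if self.config.mirror_dir is None or not self._pending_mirror:
            return
        synced = mirror_sync(self.base_dir, self.config.mirror_dir,
                             self._pending_mirror, warn=self.notify)
        self._pending_mirror = [p for p in self._pending_mirror if p not in set(synced)]

    # -------------------------------------------------------------- run loop

    def run(self, max_slices: Optional[int] = None) -> AcquisitionState:
        """Run cycles until the configured number of slices is acquired or
        the run pauses."""
        target = self.config.number_of_slices if max_slices is None else max_slices
        while self.state.status == "running" and self.state.slice_idx < target:
            self.run_slice()
        if self.state.status == "running":
            self.state.status = "finished"
            self.log(f"stack finished at slice {self.state.slice_idx}")
        return self.state
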