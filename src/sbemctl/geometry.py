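"""Coordinate transforms, stage calibration, and tile-grid layout.

Two planar coordinate frames are used throughout:

* the **SEM frame** — image-like coordinates in microns, x to the right and
  y down, in which overviews and tile grids are laid out;
* the **motor frame** — the coordinates the stage hardware actually accepts.

The motor axes are rotated and scaled with respect to the SEM frame, so a
2x2 calibration matrix maps SEM displacements to motor displacements.  The
convention fixed here: the matrix rows are the scaled, rotated motor unit
vectors,

    M = [[ scale_x * cos(angle_x),  scale_x * sin(angle_x)],
         [-scale_y * sin(angle_y),  scale_y * cos(angle_y)]]

with angles measured counterclockwise from the SEM axes.  ``stage_to_sem``
is the exact matrix inverse.

Tile grids are rows x cols arrays of frames with a configurable overlap
(negative overlap = gap).  Tile indices are 0-based (row, col); all stored
positions are frame centers; pixel rectangles are 0-based and half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .errors import E_CALIBRATION, E_CONFIG, E_DEGENERATE_INPUT, SbemError

Vec2 = Tuple[float, float]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned, half-open pixel rectangle [x, x+w) x [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError("rectangle extents must be nonnegative")

    @property
    def is_empty(self) -> bool:
        return self.w == 0 or self.h == 0

    def clip(self, width: int, height: int) -> "Rect":
        x0 = min(max(self.x, 0), width)
        y0 = min(max(self.y, 0), height)
        x1 = min(max(self.x + self.w, 0), width)
        y1 = min(max(self.y + self.h, 0), height)
        return Rect(x0, y0, max(x1 - x0, 0), max(y1 - y0, 0))

    def slices(self) -> Tuple[slice, slice]:
        """(row slice, column slice) for numpy indexing."""
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)


@dataclass
class StageCalibration:
    """Rotation/scale mapping between SEM and motor coordinates.

    Parameters
    ----------
    angle_x, angle_y : float
        Rotation of the motor X (resp. Y) axis relative to the SEM x
        (resp. y) axis, in degrees, counterclockwise.
    scale_x, scale_y : float
        Motor microns per SEM micron along each motor axis; must be > 0.
    """

    angle_x: float
    angle_y: float
    scale_x: float
    scale_y: float

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise SbemError(E_CALIBRATION, "calibration scales must be positive")

    def check_invertible(self) -> None:
        """The forward map is defined for any angles, but inversion needs a
        nonsingular matrix (the rotated axes must not be parallel)."""
        if abs(np.linalg.det(self.matrix())) < 1e-12:
            raise SbemError(E_CALIBRATION, "calibration matrix is singular")

    def matrix(self) -> np.ndarray:
        ax = math.radians(self.angle_x)
        ay = math.radians(self.angle_y)
        return np.array(
            [
                [self.scale_x * math.cos(ax), self.scale_x * math.sin(ax)],
                [-self.scale_y * math.sin(ay), self.scale_y * math.cos(ay)],
            ]
        )

    @classmethod
    def identity(cls) -> "StageCalibration":
        return cls(0.0, 0.0, 1.0, 1.0)


def sem_to_stage(p: Vec2, calib: StageCalibration) -> Vec2:
    """Map a SEM-frame point/displacement (microns) to motor coordinates."""
    m = calib.matrix() @ np.asarray(p, dtype=float)
    return (float(m[0]), float(m[1]))


def stage_to_sem(p: Vec2, calib: StageCalibration) -> Vec2:
    """Exact inverse of :func:`sem_to_stage`."""
    calib.check_invertible()
    s = np.linalg.solve(calib.matrix(), np.asarray(p, dtype=float))
    return (float(s[0]), float(s[1]))


def estimate_calibration(pairs: Iterable[Tuple[Vec2, Vec2]]) -> StageCalibration:
    """Least-squares stage calibration from displacement measurements.

    Parameters
    ----------
    pairs : iterable of ((sx, sy), (mx, my))
        Commanded SEM displacements and the motor displacements measured
        for them.  At least two pairs with non-collinear SEM displacements
        are required.

    Each motor axis is fit by ordinary least squares: motor_x = p*sx + q*sy
    gives scale_x = hypot(p, q) and angle_x = atan2(q, p); the second row is
    treated analogously with its sign convention.  On noise-free inputs this
    inverts the forward transform exactly.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise SbemError(E_DEGENERATE_INPUT, "need at least two displacement pairs")
    S = np.array([p[0] for p in pairs], dtype=float)
    M = np.array([p[1] for p in pairs], dtype=float)
    if np.linalg.matrix_rank(S, tol=1e-9 * max(1.0, float(np.abs(S).max()))) < 2:
        raise SbemError(E_DEGENERATE_INPUT, "SEM displacements are collinear")
    sol, *_ = np.linalg.lstsq(S, M, rcond=None)
    p, r = sol[0]  # coefficients of sx in motor_x, motor_y
    q, s = sol[1]  # coefficients of sy
    scale_x = math.hypot(p, q)
    scale_y = math.hypot(r, s)
    angle_x = math.degrees(math.atan2(q, p))
    angle_y = math.degrees(math.atan2(-r, s))
    return StageCalibration(angle_x, angle_y, scale_x, scale_y)


@dataclass
class TileGrid:
    """Geometry and per-tile state of one acquisition grid."""

    grid_id: int
    origin_sem: Vec2
    rows: int
    cols: int
    frame_size: Tuple[int, int]  # (width, height) px
    pixel_size: float  # nm
    overlap: int = 0  # px; negative = gap
    dwell_time: float = 0.8  # us
    active: Optional[Set[Tuple[int, int]]] = None  # None = all tiles active
    acquisition_interval: int = 1
    interval_offset: int = 0
    wd_override: Dict[Tuple[int, int], float] = field(default_factory=dict)
    gradient: Optional[object] = None  # focus.FocusGradient

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise SbemError(E_CONFIG, f"grid {self.grid_id}: rows and cols must be >= 1")
        if self.pixel_size <= 0:
            raise SbemError(E_CONFIG, f"grid {self.grid_id}: pixel_size must be > 0")
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise SbemError(E_CONFIG, f"grid {self.grid_id}: frame_size must be positive")
        if self.active is None:
            self.active = {(r, c) for r in range(self.rows) for c in range(self.cols)}
        else:
            self.active = set(self.active)
            bad = [t for t in self.active if not (0 <= t[0] < self.rows and 0 <= t[1] < self.cols)]
            if bad:
                raise SbemError(E_CONFIG, f"grid {self.grid_id}: active tiles out of range: {bad}")

    @property
    def pitch_um(self) -> Vec2:
        """Center-to-center tile spacing (x, y) in microns."""
        w, h = self.frame_size
        if self.overlap >= min(w, h):
            raise SbemError(E_CONFIG, f"grid {self.grid_id}: overlap >= frame dimension")
        return ((w - self.overlap) * self.pixel_size / 1000.0,
                (h - self.overlap) * self.pixel_size / 1000.0)

    def tile_center(self, row: int, col: int) -> Vec2:
        px, py = self.pitch_um
        return (self.origin_sem[0] + col * px, self.origin_sem[1] + row * py)

    def active_sorted(self) -> List[Tuple[int, int]]:
        """Active tiles in row-major acquisition order."""
        return sorted(self.active)


def tile_positions(grid: TileGrid) -> Dict[Tuple[int, int], Vec2]:
    """SEM-frame center position of every tile (active or not)."""
    return {(r, c): grid.tile_center(r, c)
            for r in range(grid.rows) for c in range(grid.cols)}


@dataclass
class OverviewSpec:
    """A mid-resolution overview image used for navigation and debris checks."""

    ov_id: int
    center_sem: Vec2
    frame_size: Tuple[int, int]
    pixel_size: float  # nm, typically 100-200
    acquisition_interval: int = 1
    interval_offset: int = 0
    detection_region: Optional[Rect] = None  # None = full frame
    dwell_time: float = 0.8

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise SbemError(E_CONFIG, f"overview {self.ov_id}: pixel_size must be > 0")
        w, h = self.frame_size
        if self.detection_region is None:
            self.detection_region = Rect(0, 0, w, h)
        r = self.detection_region
        if not (0 <= r.x and r.x + r.w <= w and 0 <= r.y and r.y + r.h <= h):
            raise SbemError(E_CONFIG, f"overview {self.ov_id}: detection_region outside frame")

    def top_left_sem(self) -> Vec2:
        """SEM position of the top-left corner of pixel (0, 0)."""
        w, h = self.frame_size
        ps = self.pixel_size / 1000.0
        return (self.center_sem[0] - w * ps / 2.0, self.center_sem[1] - h * ps / 2.0)

    def sem_to_pixel(self, p: Vec2) -> Tuple[float, float]:
        """Continuous overview pixel coordinates of a SEM point."""
        x0, y0 = self.top_left_sem()
        ps = self.pixel_size / 1000.0
        return ((p[0] - x0) / ps, (p[1] - y0) / ps)


# 372 nm: pixel size of the whole-stub mosaic used to locate the sample.
STUB_PIXEL_SIZE_NM = 372.0


@dataclass
class StubOverviewSpec:
    """Large low-resolution mosaic of the entire sample holder surface."""

    center_sem: Vec2 = (0.0, 0.0)
    size: Vec2 = (400.0, 300.0)  # microns
    pixel_size: float = STUB_PIXEL_SIZE_NM

    def frame_px(self) -> Tuple[int, int]:
        ps = self.pixel_size / 1000.0
        return (max(1, round(self.size[0] / ps)), max(1, round(self.size[1] / ps)))


class EmptyRegionError(SbemError):
    """No active tiles intersect the overview; caller should fall back to
    the full detection region."""

    def __init__(self) -> None:
        super().__init__(E_CONFIG, "no active tiles to bound")


def active_bounding_region(grid: TileGrid, ov: OverviewSpec) -> Rect:
    """Smallest overview-pixel rectangle covering all active tile footprints.

    Used to restrict debris detection to the part of the overview that
    actually contains tiles scheduled for acquisition, clipped to the
    overview frame.  Raises :class:`EmptyRegionError` when the grid has no
    active tiles.
    """
    if not grid.active:
        raise EmptyRegionError()
    tw = grid.frame_size[0] * grid.pixel_size / 1000.0  # tile extent, um
    th = grid.frame_size[1] * grid.pixel_size / 1000.0
    xs: List[float] = []
    ys: List[float] = []
    for (r, c) in grid.active:
        cx, cy = grid.tile_center(r, c)
        for corner in ((cx - tw / 2, cy - th / 2), (cx + tw / 2, cy + th / 2)):
            px, py = ov.sem_to_pixel(corner)
            xs.append(px)
            ys.append(py)
    x0 = math.floor(min(xs))
    y0 = math.floor(min(ys))
    x1 = math.ceil(max(xs))
    y1 = math.ceil(max(ys))
    w, h = ov.frame_size
    rect = Rect(x0, y0, x1 - x0, y1 - y0).clip(w, h)
    if rect.is_empty:
        raise EmptyRegionError()
    return rect
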