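"""Focus control: sharpness scoring, through-focus series, focus-gradient
(tilted surface) correction, and the continuous heuristic autofocus.

Working distance (WD, millimeters) is the focus control variable.  A slight
tilt of the in-chamber knife is usually unavoidable and leaves the block
surface tilted relative to the focal plane; the focus gradient fits a plane
WD(x, y) = a*x + b*y + c through three measured reference points and
evaluates it at every tile center.

The continuous autofocus estimates defocus from the width of the central
peak of the image autocorrelation (a wider peak means more blur) and
applies small WD corrections after tiles have been acquired, so it costs no
extra beam exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import E_DEGENERATE_INPUT, SbemError
from .geometry import Vec2

# Frame size of the through-focus series (width, height) in pixels.
THROUGH_FOCUS_FRAME = (512, 384)


def sharpness_score(img: np.ndarray) -> float:
    """Contrast-invariant gradient energy; higher = sharper.

    Mean squared first difference along both image axes, normalized by the
    squared image mean.  A constant image scores 0.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be 2D with at least 2 pixels per axis")
    m = a.mean()
    dx = np.diff(a, axis=1)
    dy = np.diff(a, axis=0)
    energy = (dx ** 2).mean() + (dy ** 2).mean()
    if m == 0.0:
        return 0.0 if energy == 0.0 else float(energy)
    return float(energy / m ** 2)


def through_focus_series(acquire: Callable[[float, Tuple[int, int]], np.ndarray],
                         wd_center: float, wd_step: float,
                         n_frames: int = 9) -> Tuple[List[np.ndarray], int]:
    """Acquire a small through-focus series and pick the sharpest frame.

    Frames are acquired at wd_center + k*wd_step for k = -(n-1)/2 .. +(n-1)/2,
    each 512x384 px and each exactly once (to minimize electron dose).
    Returns the frames and the 0-based index maximizing sharpness.
    """
    if n_frames < 3 or n_frames % 2 == 0:
        raise SbemError(E_DEGENERATE_INPUT, "n_frames must be an odd integer >= 3")
    half = (n_frames - 1) // 2
    frames = [acquire(wd_center + k * wd_step, THROUGH_FOCUS_FRAME)
              for k in range(-half, half + 1)]
    scores = [sharpness_score(f) for f in frames]
    return frames, int(np.argmax(scores))


def interpolate_best_index(scores: Sequence[float], best: int) -> float:
    """Sub-step refinement of a through-focus peak.

    Fits a parabola through the sharpness scores at the best frame and its
    two neighbors and returns the fractional index of the vertex (clamped
    to +-0.5 around ``best``; edge frames return ``best`` unchanged).
    """
    if best <= 0 or best >= len(scores) - 1:
        return float(best)
    s_prev, s0, s_next = scores[best - 1], scores[best], scores[best + 1]
    denom = s_prev - 2.0 * s0 + s_next
    if denom == 0:
        return float(best)
    delta = 0.5 * (s_prev - s_next) / denom
    return best + float(np.clip(delta, -0.5, 0.5))


@dataclass
class FocusGradient:
    """Plane WD(x, y) = a*x + b*y + c through three reference points.

    Positions in microns (SEM frame), working distances in millimeters.
    """

    ref_points: Tuple[Tuple[Vec2, float], ...]
    a: float
    b: float
    c: float

    def wd_at(self, p: Vec2) -> float:
        return self.a * p[0] + self.b * p[1] + self.c


def fit_focus_gradient(points: Sequence[Tuple[Vec2, float]]) -> FocusGradient:
    """Fit the unique focus plane through three non-collinear (x, y, wd)
    reference measurements."""
    if len(points) != 3:
        raise SbemError(E_DEGENERATE_INPUT, "exactly three reference points required")
    A = np.array([[p[0][0], p[0][1], 1.0] for p in points])
    wds = np.array([p[1] for p in points])
    det = np.linalg.det(A)
    span = max(1.0, float(np.abs(A[:, :2]).max()) ** 2)
    if abs(det) < 1e-9 * span:
        raise SbemError(E_DEGENERATE_INPUT, "reference points are collinear")
    a, b, c = np.linalg.solve(A, wds)
    return FocusGradient(tuple((tuple(p[0]), float(p[1])) for p in points),
                         float(a), float(b), float(c))


def wd_for_tile(grid, row: int, col: int, fallback_wd: float) -> float:
    """Working distance for one tile: per-tile override > gradient plane >
    global focus state."""
    key = (row, col)
    if key in grid.wd_override:
        return grid.wd_override[key]
    if grid.gradient is not None:
        return grid.gradient.wd_at(grid.tile_center(row, col))
    return fallback_wd


@dataclass
class FocusState:
    """Current focus/stigmation state plus autofocus controller memory.

    Stigmation is carried as state (percent) but has no optical model.
    """

    wd: float  # mm
    stig_x: float = 0.0
    stig_y: float = 0.0
    drift_log: List[float] = field(default_factory=list)
    # controller internals
    best_width: Optional[float] = None
    last_width: Optional[float] = None
    direction: float = 1.0

    def __post_init__(self) -> None:
        if self.wd <= 0:
            raise ValueError("working distance must be > 0")


def autocorrelation_halfwidth(img: np.ndarray) -> float:
    """Half-width at half maximum of the central autocorrelation peak,
    averaged over the two axes, in pixels (sub-pixel interpolated).

    Blur widens the peak monotonically, so this is a (unsigned) defocus
    proxy.  A constant image returns 0.
    """
    a = np.asarray(img, dtype=np.float64)
    a = a - a.mean()
    if not np.any(a):
        return 0.0
    f = np.fft.rfft2(a)
    acf = np.fft.irfft2(np.abs(f) ** 2, s=a.shape)

    def _halfwidth(profile: np.ndarray) -> float:
        # White detector noise only contributes to the zero lag, so the
        # peak is normalized at lag 1 and measured from there.
        ref = profile[1]
        if ref <= 0:
            return 1.0
        half = 0.5 * ref
        n = profile.size
        for i in range(2, n):
            if profile[i] < half:
                p0, p1 = profile[i - 1], profile[i]
                return (i - 1) + (p0 - half) / (p0 - p1)
        return float(n - 1)

    wx = _halfwidth(acf[0, : acf.shape[1] // 2])
    wy = _halfwidth(acf[: acf.shape[0] // 2, 0])
    return 0.5 * (wx + wy)


def heuristic_autofocus_update(tile_img: np.ndarray, state: FocusState,
                               gain: float = 5e-4, max_step: float = 0.002,
                               width_tol: float = 0.05) -> FocusState:
    """One step of the continuous autofocus, applied after a tile was
    acquired at the current working distance.

    Extremum-seeking controller on the autocorrelation peak half-width w:
    the sharpest state seen defines the target width; the correction
    magnitude is gain * (w - best_w), clipped to +-max_step, and the sign
    is flipped whenever the width grew since the previous step (i.e. the
    last correction moved away from focus).  gain is in mm per pixel of
    excess width.  With gain = 0 the state is unchanged.
    """
    w = autocorrelation_halfwidth(tile_img)
    if gain == 0.0:
        return state
    if state.best_width is None or w < state.best_width:
        state.best_width = w
    excess = w - state.best_width
    if state.last_width is not None and w > state.last_width + width_tol:
        state.direction *= -1.0
    state.last_width = w
    step = float(np.clip(gain * excess, 0.0, max_step)) * state.direction
    state.wd += step
    state.drift_log.append(step)
    return state


def periodic_autofocus_due(slice_idx: int, interval: int,
                           ref_tiles: Set[Tuple[int, int]],
                           offset: int = 0) -> Set[Tuple[int, int]]:
    """Reference tiles due for a scheduled (vendor) autofocus pass.

    Autofocus and autostigmation can be scheduled on the same slice or a
    number of slices apart via different offsets.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if (slice_idx - offset) % interval == 0:
        return set(ref_tiles)
    return set()
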