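"""Slice-by-slice tile monitoring and image inspection.

Every acquired tile is reduced to its mean and standard deviation; sudden
changes between the same tile on consecutive slices (loss of focus,
darkening, blank frames) pause the acquisition.  Each written image file is
also read back and checked for integrity (decodable, expected size,
non-uniform, statistics in range) before it counts as acquired.  Previews,
reslices and histograms support visual QC of a running or finished stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

from .errors import E_DIMENSION_MISMATCH, E_UNREADABLE_FILE, SbemError

PREVIEW_SIZE = (512, 384)  # (width, height) px


@dataclass(frozen=True)
class TileStats:
    slice_idx: int
    grid_id: int
    row: int
    col: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def compute_stats(img: np.ndarray, slice_idx: int, grid_id: int,
                  row: int, col: int) -> TileStats:
    a = np.asarray(img, dtype=np.float64)
    return TileStats(slice_idx, grid_id, row, col, float(a.mean()), float(a.std()))


def tile_delta_check(prev: TileStats, curr: TileStats,
                     mean_threshold: float, sd_threshold: float) -> str:
    """Compare a tile's statistics against the same tile one slice earlier.

    Returns ``"pass"`` or ``"pause"``; thresholds are strict (a change
    exactly equal to the threshold passes).
    """
    if abs(curr.mean - prev.mean) > mean_threshold:
        return "pause"
    if abs(curr.sd - prev.sd) > sd_threshold:
        return "pause"
    return "pass"


@dataclass
class InspectionResult:
    checks: List[Tuple[str, bool, str]] = field(default_factory=list)
    accepted: bool = True
    action: str = "keep"  # keep | discard | pause
    stats: Optional[Tuple[float, float]] = None  # (mean, sd)

    def failed(self) -> List[str]:
        return [name for name, ok, _ in self.checks if not ok]


RangeLimits = Tuple[float, float, float, float]  # mean_min, mean_max, sd_min, sd_max


def inspect_image(path_or_image: Union[str, Path, np.ndarray],
                  expected_size: Tuple[int, int],
                  range_limits: RangeLimits,
                  user_predicate: Optional[Callable[[np.ndarray], bool]] = None,
                  ) -> InspectionResult:
    """Integrity and quality checks on an acquired image.

    Mandatory checks (any failure -> action "pause"): the file exists and
    decodes; dimensions equal ``expected_size`` (width, height); the image
    is not uniform; mean and SD lie within ``range_limits``.  An optional
    user predicate only selects (keep) or discards accepted images, e.g. to
    save storage; it never pauses the run.
    """
    result = InspectionResult()

    if isinstance(path_or_image, (str, Path)):
        try:
            img = tifffile.imread(str(path_or_image))
            result.checks.append(("readable", True, str(path_or_image)))
        except (OSError, ValueError) as exc:
            raise SbemError(E_UNREADABLE_FILE, f"cannot read {path_or_image}: {exc}")
    else:
        img = np.asarray(path_or_image)

    w, h = expected_size
    dims_ok = img.ndim == 2 and img.shape == (h, w)
    result.checks.append(("dimensions", dims_ok, f"got {img.shape}, want {(h, w)}"))
    if not dims_ok:
        result.accepted = False
        result.action = "pause"
        return result

    a = img.astype(np.float64)
    mean, sd = float(a.mean()), float(a.std())
    result.stats = (mean, sd)
    uniform_ok = sd > 0.0
    result.checks.append(("not_uniform", uniform_ok, f"sd={sd:.4g}"))
    mean_min, mean_max, sd_min, sd_max = range_limits
    range_ok = (mean_min <= mean <= mean_max) and (sd_min <= sd <= sd_max)
    result.checks.append(("stats_in_range", range_ok,
                          f"mean={mean:.2f} in [{mean_min},{mean_max}], "
                          f"sd={sd:.2f} in [{sd_min},{sd_max}]"))
    if not (uniform_ok and range_ok):
        result.accepted = False
        result.action = "pause"
        return result

    if user_predicate is not None and not user_predicate(img):
        result.checks.append(("user_predicate", False, "discarded by user check"))
        result.action = "discard"
    return result


def make_preview(img: np.ndarray, warn: Optional[Callable[[str], None]] = None) -> np.ndarray:
    """Reduce a tile to the 512x384 preview generated right after each
    acquisition.

    Uses block-mean downsampling when the source is an integer multiple of
    the preview size; otherwise a local-mean resampling over fractional
    blocks.  Sources smaller than the preview are passed through unchanged
    with a warning.
    """
    a = np.asarray(img, dtype=np.float64)
    h, w = a.shape
    tw, th = PREVIEW_SIZE
    if w < tw or h < th:
        if warn is not None:
            warn(f"source {w}x{h} smaller than preview {tw}x{th}; pass-through")
        return np.asarray(img).copy()
    if w % tw == 0 and h % th == 0:
        fy, fx = h // th, w // tw
        out = a.reshape(th, fy, tw, fx).mean(axis=(1, 3))
    else:
        # local mean via cumulative sums on fractional block edges
        ys = np.linspace(0, h, th + 1)
        xs = np.linspace(0, w, tw + 1)
        ii = np.pad(a.cumsum(0).cumsum(1), ((1, 0), (1, 0)))

        def _at(yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
            y0 = np.floor(yy).astype(int)
            x0 = np.floor(xx).astype(int)
            fyy = (yy - y0)[:, None]
            fxx = (xx - x0)[None, :]
            v00 = ii[np.ix_(y0, x0)]
            v01 = ii[np.ix_(y0, np.minimum(x0 + 1, w))]
            v10 = ii[np.ix_(np.minimum(y0 + 1, h), x0)]
            v11 = ii[np.ix_(np.minimum(y0 + 1, h), np.minimum(x0 + 1, w))]
            return (v00 * (1 - fyy) * (1 - fxx) + v01 * (1 - fyy) * fxx
                    + v10 * fyy * (1 - fxx) + v11 * fyy * fxx)

        s = (_at(ys[1:], xs[1:]) - _at(ys[:-1], xs[1:])
             - _at(ys[1:], xs[:-1]) + _at(ys[:-1], xs[:-1]))
        area = np.outer(np.diff(ys), np.diff(xs))
        out = s / area
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        info = np.iinfo(np.asarray(img).dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(np.asarray(img).dtype)
    return out


def reslice(tile_history: Sequence[np.ndarray], line: Optional[int] = None) -> np.ndarray:
    """z-profile through one tile's stack: row k of the output is a fixed
    pixel row (default: the central row) of the tile image at slice k."""
    if len(tile_history) == 0:
        raise SbemError(E_DIMENSION_MISMATCH, "need at least one slice")
    shape = np.asarray(tile_history[0]).shape
    rows = []
    for img in tile_history:
        a = np.asarray(img)
        if a.shape != shape:
            raise SbemError(E_DIMENSION_MISMATCH,
                            f"inconsistent tile dimensions: {a.shape} vs {shape}")
        r = shape[0] // 2 if line is None else line
        rows.append(a[r, :])
    return np.stack(rows, axis=0)


def histogram(img: np.ndarray, bins: int = 256) -> np.ndarray:
    """Gray-level histogram over the full bit-depth range; counts sum to
    the pixel count."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    a = np.asarray(img)
    if np.issubdtype(a.dtype, np.integer):
        top = float(np.iinfo(a.dtype).max) + 1.0
    else:
        top = float(max(a.max(), 1.0)) + 1.0
    counts, _ = np.histogram(a, bins=bins, range=(0.0, top))
    return counts
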