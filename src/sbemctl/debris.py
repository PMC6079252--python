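"""Debris detection on consecutive overview images, and the sweep loop.

Debris falling on the block face obscures the region of interest; every new
overview is compared against the last accepted (clean) overview of the same
region.  Three detectors are available:

``quadrant_meansd`` (default)
    The detection region is split into four quadrants; per quadrant the
    absolute change in pixel mean and standard deviation is computed.
    Debris is flagged when any quadrant exceeds the mean threshold or the
    SD threshold.
``histogram``
    Total variation distance between the normalized gray-level histograms
    of the region (range [0, 1]).
``pixel_diff``
    Fraction of region pixels whose absolute change exceeds a per-pixel
    delta.

When debris is flagged, the sample is lowered by a small depth (default
70 nm) and the knife is swept across the surface to push the debris away,
then the overview is re-acquired and re-tested, up to a configured maximum
number of sweeps.

All thresholds are strict (a difference exactly equal to the threshold does
not trigger) and should be fine-tuned per sample and imaging settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .errors import E_DIMENSION_MISMATCH, SbemError
from .geometry import Rect

# Depth by which the sample is lowered before a debris-removal knife sweep.
DEFAULT_SWEEP_DEPTH_NM = 70.0

METHODS = ("quadrant_meansd", "histogram", "pixel_diff")


@dataclass
class DebrisReport:
    """Outcome of one debris comparison.

    ``per_region_diffs`` holds the raw statistics (for the quadrant method:
    four |dMean| then four |dSD| values).  ``max_diff`` and ``threshold``
    are expressed in a single common unit so that ``debris_detected`` is
    always equivalent to ``max_diff > threshold``; for the quadrant method
    SD differences are rescaled by mean_threshold/sd_threshold to that end.
    """

    method: str
    per_region_diffs: List[float]
    max_diff: float
    threshold: float
    debris_detected: bool
    region: Rect

    def __post_init__(self) -> None:
        assert self.method in METHODS
        assert self.debris_detected == (self.max_diff > self.threshold)


def _check_pair(prev: np.ndarray, curr: np.ndarray, region: Rect) -> Tuple[np.ndarray, np.ndarray]:
    if prev.shape != curr.shape:
        raise SbemError(E_DIMENSION_MISMATCH,
                        f"image dimensions differ: {prev.shape} vs {curr.shape}")
    if region.is_empty:
        raise SbemError(E_DIMENSION_MISMATCH, "empty detection region")
    ry, rx = region.slices()
    a = np.asarray(prev, dtype=np.float64)[ry, rx]
    b = np.asarray(curr, dtype=np.float64)[ry, rx]
    if a.size == 0:
        raise SbemError(E_DIMENSION_MISMATCH, "detection region outside image")
    return a, b


def _quadrants(img: np.ndarray) -> List[np.ndarray]:
    # Odd extents: the extra row/column goes to the lower/right quadrants.
    h, w = img.shape
    hs, ws = h // 2, w // 2
    return [img[:hs, :ws], img[:hs, ws:], img[hs:, :ws], img[hs:, ws:]]


def detect_debris_quadrant(prev: np.ndarray, curr: np.ndarray, region: Rect,
                           mean_threshold: float = 10.0,
                           sd_threshold: float = 10.0) -> DebrisReport:
    """Default detector: per-quadrant mean/SD comparison."""
    a, b = _check_pair(prev, curr, region)
    dmeans = []
    dsds = []
    for qa, qb in zip(_quadrants(a), _quadrants(b)):
        if qa.size == 0:
            dmeans.append(0.0)
            dsds.append(0.0)
            continue
        dmeans.append(abs(float(qb.mean()) - float(qa.mean())))
        dsds.append(abs(float(qb.std()) - float(qa.std())))
    diffs = dmeans + dsds
    # Common unit: SD differences expressed in mean-threshold units.
    ratio = mean_threshold / sd_threshold if sd_threshold > 0 else np.inf
    max_diff = max(dmeans + [d * ratio for d in dsds])
    return DebrisReport(
        method="quadrant_meansd",
        per_region_diffs=diffs,
        max_diff=float(max_diff),
        threshold=float(mean_threshold),
        debris_detected=bool(max_diff > mean_threshold),
        region=region,
    )


def detect_debris_histogram(prev: np.ndarray, curr: np.ndarray, region: Rect,
                            threshold: float = 0.10, bins: int = 256,
                            value_range: Tuple[float, float] = (0, 256)) -> DebrisReport:
    """Histogram detector: total variation distance between gray-level
    histograms normalized to unit mass."""
    a, b = _check_pair(prev, curr, region)
    ha, _ = np.histogram(a, bins=bins, range=value_range)
    hb, _ = np.histogram(b, bins=bins, range=value_range)
    n = a.size
    tv = 0.5 * float(np.abs(ha / n - hb / n).sum())
    return DebrisReport(
        method="histogram",
        per_region_diffs=[tv],
        max_diff=tv,
        threshold=float(threshold),
        debris_detected=bool(tv > threshold),
        region=region,
    )


def detect_debris_pixel(prev: np.ndarray, curr: np.ndarray, region: Rect,
                        pixel_delta: float = 25.0,
                        fraction_threshold: float = 0.05) -> DebrisReport:
    """Pixel-difference detector: fraction of pixels changed by more than
    ``pixel_delta`` gray levels (strictly)."""
    a, b = _check_pair(prev, curr, region)
    frac = float((np.abs(b - a) > pixel_delta).mean())
    return DebrisReport(
        method="pixel_diff",
        per_region_diffs=[frac],
        max_diff=frac,
        threshold=float(fraction_threshold),
        debris_detected=bool(frac > fraction_threshold),
        region=region,
    )


@dataclass
class SweepPolicy:
    """How to react when debris is detected."""

    depth: float = DEFAULT_SWEEP_DEPTH_NM  # nm the sample is lowered per sweep
    max_sweeps: int = 3
    continue_after_max: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("sweep depth must be > 0")
        if self.max_sweeps < 0:
            raise ValueError("max_sweeps must be >= 0")


@dataclass
class SweepOutcome:
    status: str  # clean | continued_with_debris | paused
    sweeps: int
    final_image: np.ndarray
    reports: List[DebrisReport] = field(default_factory=list)


def sweep_until_clean(acquire_overview: Callable[[], np.ndarray],
                      sweep: Callable[[float], None],
                      reference: np.ndarray,
                      first_image: np.ndarray,
                      detect: Callable[[np.ndarray, np.ndarray], DebrisReport],
                      policy: SweepPolicy,
                      log: Optional[Callable[[str], None]] = None) -> SweepOutcome:
    """Run the debris-removal loop for one overview on one slice.

    ``reference`` is the last accepted debris-free overview of the same
    region; ``first_image`` is the overview just acquired on this slice.
    While debris is detected and sweeps remain, the sample is lowered by
    ``policy.depth`` nm, the knife is swept, and the overview re-acquired.
    Never issues more than ``policy.max_sweeps`` sweep commands.
    """
    img = first_image
    reports: List[DebrisReport] = []
    sweeps = 0
    while True:
        report = detect(reference, img)
        reports.append(report)
        if not report.debris_detected:
            return SweepOutcome("clean", sweeps, img, reports)
        if sweeps >= policy.max_sweeps:
            status = "continued_with_debris" if policy.continue_after_max else "paused"
            return SweepOutcome(status, sweeps, img, reports)
        sweep(policy.depth)
        sweeps += 1
        if log is not None:
            log(f"debris sweep {sweeps}/{policy.max_sweeps} "
                f"(max_diff={report.max_diff:.3f} > {report.threshold:.3f})")
        img = acquire_overview()
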