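import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sbemctl.debris import (SweepPolicy, detect_debris_histogram,
                            detect_debris_pixel, detect_debris_quadrant,
                            sweep_until_clean)
from sbemctl.errors import SbemError
from sbemctl.geometry import Rect

FULL = Rect(0, 0, 80, 60)

images = hnp.arrays(np.uint8, (60, 80),
                    elements=st.integers(0, 255))

DETECTORS = [
    lambda a, b: detect_debris_quadrant(a, b, FULL, 10.0, 10.0),
    lambda a, b: detect_debris_histogram(a, b, FULL, 0.10),
    lambda a, b: detect_debris_pixel(a, b, FULL, 25.0, 0.05),
]


@pytest.mark.parametrize("detect", DETECTORS, ids=["quadrant", "histogram", "pixel"])
@given(img=images)
def test_identical_images_never_flag_debris(detect, img):
    report = detect(img, img)
    assert not report.debris_detected
    assert report.max_diff == 0.0


@pytest.mark.parametrize("detect", DETECTORS, ids=["quadrant", "histogram", "pixel"])
@given(a=images, b=images)
def test_detection_symmetric_in_magnitude(detect, a, b):
    assert detect(a, b).max_diff == pytest.approx(detect(b, a).max_diff)


class TestQuadrant:
    def test_single_quadrant_offset_detected_with_exact_mean(self, rng):
        prev = rng.integers(40, 200, (60, 80)).astype(np.uint8)
        curr = prev.copy().astype(np.int16)
        curr[:30, :40] += 30  # raise the top-left quadrant by 30 gray levels
        report = detect_debris_quadrant(prev, curr, FULL, 10.0, 10.0)
        assert report.debris_detected
        assert max(report.per_region_diffs[:4]) == pytest.approx(30.0)

    def test_uniform_offset_below_threshold_passes(self, rng):
        prev = rng.integers(40, 200, (60, 80)).astype(np.float64)
        report = detect_debris_quadrant(prev, prev + 5.0, FULL, 10.0, 10.0)
        assert not report.debris_detected
        assert report.per_region_diffs[:4] == pytest.approx([5.0] * 4)

    def test_sd_change_alone_triggers(self, rng):
        prev = np.full((60, 80), 100.0)
        curr = prev.copy()
        curr[:30, :40] += rng.normal(0, 40, (30, 40))  # SD jump, mean ~ same
        report = detect_debris_quadrant(prev, curr, FULL, 1000.0, 10.0)
        assert report.debris_detected

    def test_odd_extents_split_extra_to_lower_right(self):
        # 5x5 region: quadrants are 2x2, 2x3, 3x2, 3x3
        prev = np.zeros((5, 5))
        curr = np.zeros((5, 5))
        curr[2:, 2:] = 12.0  # exactly the lower-right 3x3 quadrant
        report = detect_debris_quadrant(prev, curr, Rect(0, 0, 5, 5), 10.0, 10.0)
        assert report.per_region_diffs[:4] == pytest.approx([0, 0, 0, 12.0])

    def test_dimension_mismatch_is_inspection_error(self):
        with pytest.raises(SbemError) as exc:
            detect_debris_quadrant(np.zeros((10, 10)), np.zeros((9, 10)),
                                   Rect(0, 0, 9, 9), 10, 10)
        assert exc.value.group == 5


class TestHistogram:
    def test_disjoint_uniform_histograms_distance_one(self):
        prev = np.full((60, 80), 100, np.uint8)
        curr = np.full((60, 80), 200, np.uint8)
        report = detect_debris_histogram(prev, curr, FULL, 0.10)
        assert report.max_diff == pytest.approx(1.0)
        assert report.debris_detected

    def test_quarter_replacement_distance(self):
        # hand-computed total variation: moving 25% of the mass is 0.25
        prev = np.full((60, 80), 100, np.uint8)
        curr = prev.copy()
        curr[:30, :40] = 220  # 1200 of 4800 pixels
        report = detect_debris_histogram(prev, curr, FULL, 0.10)
        assert report.max_diff == pytest.approx(0.25)


class TestPixelDiff:
    def test_changed_fraction_counted(self):
        prev = np.full((60, 80), 100, np.uint8)
        curr = prev.copy()
        curr.flat[:480] = 160  # exactly 10% of 4800 pixels, change 60 > 25
        report = detect_debris_pixel(prev, curr, FULL, 25.0, 0.05)
        assert report.max_diff == pytest.approx(0.10)
        assert report.debris_detected

    def test_boundary_change_is_exclusive(self):
        prev = np.full((60, 80), 100.0)
        report = detect_debris_pixel(prev, prev + 25.0, FULL, 25.0, 0.05)
        assert report.max_diff == 0.0
        assert not report.debris_detected


class _FakeScope:
    """Minimal instrument for the sweep loop: debris vanishes after a
    configured number of sweeps (None = never)."""

    def __init__(self, clears_after):
        self.clears_after = clears_after
        self.sweeps = 0
        self.face_z = 0.0

    def sweep(self, depth):
        self.sweeps += 1
        self.face_z += depth

    def overview(self):
        img = np.full((40, 40), 100.0)
        dirty = self.clears_after is None or self.sweeps < self.clears_after
        if dirty:
            img[:20, :20] += 50.0
        return img


def _loop(scope, policy):
    detect = lambda a, b: detect_debris_quadrant(a, b, Rect(0, 0, 40, 40), 10, 10)
    return sweep_until_clean(scope.overview, scope.sweep,
                             reference=np.full((40, 40), 100.0),
                             first_image=scope.overview(),
                             detect=detect, policy=policy)


class TestSweepLoop:
    def test_clean_first_test_no_sweeps(self):
        scope = _FakeScope(clears_after=0)
        out = _loop(scope, SweepPolicy(max_sweeps=3))
        assert out.status == "clean" and out.sweeps == 0 and scope.face_z == 0.0

    def test_removable_debris_one_sweep_default_depth(self):
        scope = _FakeScope(clears_after=1)
        out = _loop(scope, SweepPolicy(max_sweeps=3))
        assert out.status == "clean" and out.sweeps == 1
        assert scope.face_z == pytest.approx(70.0)  # default lowering depth

    def test_permanent_debris_pauses_after_max(self):
        scope = _FakeScope(clears_after=None)
        out = _loop(scope, SweepPolicy(max_sweeps=2, continue_after_max=False))
        assert out.status == "paused" and out.sweeps == 2 and scope.sweeps == 2

    def test_continue_after_max_when_configured(self):
        scope = _FakeScope(clears_after=None)
        out = _loop(scope, SweepPolicy(max_sweeps=2, continue_after_max=True))
        assert out.status == "continued_with_debris" and scope.sweeps == 2

    @given(max_sweeps=st.integers(0, 5))
    def test_never_exceeds_max_sweeps(self, max_sweeps):
        scope = _FakeScope(clears_after=None)
        _loop(scope, SweepPolicy(max_sweeps=max_sweeps, continue_after_max=True))
        assert scope.sweeps <= max_sweeps


def test_simulator_detects_all_quadrant_contained_chunks(calib):
    """Medium-size chunks (>= 10% of the detection region, contrast >= 3x
    the mean threshold) lying within one quadrant are always detected."""
    from sbemctl.geometry import sem_to_stage
    from sbemctl.instrument import SemRect, SimulatorParams, VirtualInstrument

    rng = np.random.default_rng(77)
    detected = 0
    trials = 100
    region = Rect(0, 0, 120, 90)
    for _ in range(trials):
        inst = VirtualInstrument(SimulatorParams(), calib,
                                 seed=int(rng.integers(2 ** 31)))
        motor = sem_to_stage((0.0, 0.0), calib)
        prev = inst.acquire_frame(motor, (120, 90), 150.0, 0.8, 7.0)
        # overview footprint 18 x 13.5 um; quadrant 9 x 6.75 um.
        # place a chunk covering >= 40% of one quadrant (>= 10% of region)
        qx = rng.choice([-9.0, 0.0])
        qy = rng.choice([-6.75, 0.0])
        w, h = rng.uniform(6.0, 8.5), rng.uniform(4.5, 6.0)
        patch = SemRect(qx + rng.uniform(0, 9.0 - w), qy + rng.uniform(0, 6.75 - h),
                        w, h)
        inst.inject_debris(0, patch, contrast=rng.uniform(30.0, 60.0),
                           removal_probability=1.0)
        curr = inst.acquire_frame(motor, (120, 90), 150.0, 0.8, 7.0)
        report = detect_debris_quadrant(prev, curr, region, 10.0, 10.0)
        detected += report.debris_detected
    assert detected == trials
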