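import numpy as np
import pytest
from hypothesis import settings

from sbemctl.config import RunConfig, make_instrument
from sbemctl.engine import BeamParams
from sbemctl.geometry import OverviewSpec, StageCalibration, TileGrid
from sbemctl.instrument import SimulatorParams, VirtualInstrument

settings.register_profile("suite", max_examples=50, derandomize=True,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def calib():
    """A typical rotated/scaled stage calibration."""
    return StageCalibration(angle_x=30.0, angle_y=28.0, scale_x=1.02, scale_y=0.98)


@pytest.fixture
def small_grid():
    return TileGrid(0, (-8.0, -6.0), 2, 2, (64, 48), 10.0, overlap=8)


@pytest.fixture
def overview():
    return OverviewSpec(0, (0.0, 0.0), (200, 150), 150.0)


@pytest.fixture
def instrument(calib):
    return VirtualInstrument(SimulatorParams(), calib, seed=42)


@pytest.fixture
def quiet_instrument(calib):
    """Noise-free, untilted instrument for exact-value checks."""
    return VirtualInstrument(
        SimulatorParams(noise_scale=0.0, knife_tilt=(0.0, 0.0)), calib, seed=42)


@pytest.fixture
def make_config(tmp_path, calib, small_grid, overview):
    """Factory for small complete run configs rooted in tmp_path."""

    def _make(seed=7, n_slices=3, grids=None, overviews=None, **overrides):
        cfg = RunConfig(
            stack_name="t",
            base_dir=str(tmp_path / "out"),
            calibration=calib,
            grids=[small_grid] if grids is None else grids,
            overviews=[overview] if overviews is None else overviews,
            beam=BeamParams(current=270.0, dwell_time=0.8, pixel_size=10.0),
            number_of_slices=n_slices,
            seed=seed,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
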