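import collections

import numpy as np
import pytest

from sbemctl.config import make_instrument
from sbemctl.engine import (AcquisitionEngine, BeamParams, electron_dose,
                            dose_range, estimate_duration_storage,
                            schedule_due, with_retry)
from sbemctl.errors import (E_ACQUISITION_FAILURE, InstrumentFault, SbemError)
from sbemctl.geometry import OverviewSpec, TileGrid
from sbemctl.io_metadata import read_metadata
from sbemctl.scenarios import FaultyBackend


class TestScheduleDue:
    def test_interval_one_every_slice(self):
        assert all(schedule_due(s, 1) for s in range(20))

    def test_every_tenth_slice(self):
        due = [s for s in range(35) if schedule_due(s, 10)]
        assert due == [0, 10, 20, 30]

    def test_alternating_offset(self):
        # interval 2 offset 1: odd slices (alternating pixel sizes use case)
        due = [s for s in range(8) if schedule_due(s, 2, 1)]
        assert due == [1, 3, 5, 7]

    def test_invalid_offset_rejected(self):
        with pytest.raises(ValueError):
            schedule_due(0, 5, 5)


class TestWithRetry:
    def _flaky(self, fail_times):
        calls = {"n": 0}

        def action():
            calls["n"] += 1
            if calls["n"] <= fail_times:
                raise InstrumentFault(E_ACQUISITION_FAILURE, "flake")
            return "ok"

        return action, calls

    def test_first_try_success_no_warnings(self):
        action, calls = self._flaky(0)
        warnings = []
        assert with_retry(action, 3, warnings.append) == "ok"
        assert calls["n"] == 1 and warnings == []

    def test_two_failures_then_success(self):
        action, calls = self._flaky(2)
        warnings = []
        assert with_retry(action, 3, warnings.append) == "ok"
        assert calls["n"] == 3 and len(warnings) == 2

    def test_persistent_failure_raises_after_three_attempts(self):
        action, calls = self._flaky(99)
        with pytest.raises(SbemError) as exc:
            with_retry(action, 3)
        assert calls["n"] == 3 and exc.value.group == 3


class TestDose:
    def test_hand_computed_reference_beam(self):
        # (270e-12 A * 0.8e-6 s) / (1.602176634e-19 C * 100 nm^2)
        beam = BeamParams(current=270.0, dwell_time=0.8, pixel_size=10.0)
        expected = 270e-12 * 0.8e-6 / (1.602176634e-19 * 100.0)
        assert electron_dose(beam) == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_dwell_time(self):
        a = electron_dose(BeamParams(270.0, 0.8, 10.0))
        b = electron_dose(BeamParams(270.0, 1.6, 10.0))
        assert b == pytest.approx(2 * a)

    def test_inverse_square_in_pixel_size(self):
        a = electron_dose(BeamParams(270.0, 0.8, 10.0))
        b = electron_dose(BeamParams(270.0, 0.8, 5.0))
        assert b == pytest.approx(4 * a)

    def test_range_over_grids(self):
        beam = BeamParams(270.0, 0.8, 10.0)
        grids = [TileGrid(0, (0, 0), 1, 1, (64, 64), 10.0, dwell_time=0.8),
                 TileGrid(1, (0, 0), 1, 1, (64, 64), 20.0, dwell_time=1.6)]
        lo, hi = dose_range(beam, grids)
        assert lo == pytest.approx(electron_dose(BeamParams(270.0, 1.6, 20.0)))
        assert hi == pytest.approx(electron_dose(BeamParams(270.0, 0.8, 10.0)))


class TestEstimates:
    def test_nothing_scheduled_nothing_stored(self, make_config):
        cfg = make_config(grids=[], overviews=[], n_slices=5)
        seconds, nbytes = estimate_duration_storage(cfg)
        assert nbytes == 0
        assert seconds == pytest.approx(5 * cfg.cut_overhead_s)

    def test_storage_closed_form_for_large_grid(self, make_config):
        active = {(r, c) for r in range(5) for c in range(4)} - {(0, 0), (4, 3)}
        grid = TileGrid(0, (0, 0), 5, 4, (4096, 4096), 10.0, active=active)
        cfg = make_config(grids=[grid], overviews=[], n_slices=100)
        _, nbytes = estimate_duration_storage(cfg)
        assert nbytes == 18 * 4096 ** 2 * 100  # 18 active tiles, 8-bit

    def test_imaging_time_term(self, make_config):
        grid = TileGrid(0, (0, 0), 1, 1, (4096, 4096), 10.0, dwell_time=0.8)
        cfg = make_config(grids=[grid], overviews=[], n_slices=1,
                          stage_move_overhead_s=0.0, cut_overhead_s=0.0)
        seconds, _ = estimate_duration_storage(cfg)
        assert seconds == pytest.approx(4096 ** 2 * 0.8e-6)  # ~13.4 s


class TestRunCycle:
    def test_clean_run_file_and_cut_counts(self, make_config):
        cfg = make_config(n_slices=3)
        inst = make_instrument(cfg)
        engine = AcquisitionEngine(cfg, inst)
        state = engine.run()
        assert state.status == "finished" and state.slice_idx == 3
        tile_recs = [r for r in read_metadata(engine.base_dir) if r.grid_id >= 0]
        assert len(tile_recs) == 12  # 2x2 tiles x 3 slices
        assert inst.count_commands("CUT") == 3

    def test_only_active_tiles_acquired(self, make_config, calib):
        grid = TileGrid(0, (-8.0, -6.0), 2, 2, (64, 48), 10.0,
                        active={(0, 0), (1, 1)})
        cfg = make_config(grids=[grid], n_slices=2)
        engine = AcquisitionEngine(cfg, make_instrument(cfg))
        engine.run()
        recs = [r for r in read_metadata(engine.base_dir) if r.grid_id >= 0]
        assert {(r.row, r.col) for r in recs} == {(0, 0), (1, 1)}
        assert len(recs) == 4

    def test_pause_sentinel_stops_before_any_acquisition(self, make_config):
        cfg = make_config(n_slices=3)
        inst = make_instrument(cfg)
        engine = AcquisitionEngine(cfg, inst)
        (engine.base_dir / "pause.cmd").touch()
        engine.run_slice()
        assert engine.state.status == "paused"
        assert inst.count_commands("ACQUIRE") == 0

    def test_resume_never_reacquires_tiles(self, make_config):
        cfg = make_config(n_slices=3)
        inst = make_instrument(cfg)
        engine = AcquisitionEngine(cfg, FaultyBackend(inst, fail_at=9))
        for _ in range(5):
            engine.run()
            if engine.state.status == "finished":
                break
            engine.resume()
        assert engine.state.status == "finished"
        counts = collections.Counter(
            (r.slice_idx, r.row, r.col)
            for r in read_metadata(engine.base_dir) if r.grid_id >= 0)
        assert len(counts) == 12 and set(counts.values()) == {1}

    def test_blank_tile_event_pauses_at_that_slice(self, make_config):
        cfg = make_config(n_slices=50, overviews=[])  # next frame is a tile
        inst = make_instrument(cfg)
        engine = AcquisitionEngine(cfg, inst)
        for _ in range(7):  # run 7 clean slices
            engine.run_slice()
        inst.inject_fault("blank", 1)  # beam blanked: next frame is black
        engine.run()
        assert engine.state.status == "paused"
        assert engine.state.slice_idx == 7
        assert engine.state.error_code is not None
        assert engine.state.error_code // 100 == 5

    def test_grid_interval_scheduling(self, make_config, small_grid):
        small_grid.acquisition_interval = 2
        cfg = make_config(grids=[small_grid], n_slices=4)
        engine = AcquisitionEngine(cfg, make_instrument(cfg))
        engine.run()
        recs = [r for r in read_metadata(engine.base_dir) if r.grid_id >= 0]
        assert sorted({r.slice_idx for r in recs}) == [0, 2]

    def test_mirror_matches_primary_after_clean_run(self, make_config, tmp_path):
        from sbemctl.io_metadata import file_checksum
        cfg = make_config(n_slices=2, mirror_dir=str(tmp_path / "mirror"))
        engine = AcquisitionEngine(cfg, make_instrument(cfg))
        engine.run()
        primary = sorted(p.relative_to(engine.base_dir)
                         for p in engine.base_dir.rglob("*.tif"))
        assert primary
        for rel in primary:
            assert file_checksum(engine.base_dir / rel) == file_checksum(
                tmp_path / "mirror" / rel)

    def test_mirror_failure_warns_but_run_continues(self, make_config, tmp_path):
        blocker = tmp_path / "blocked"
        blocker.write_text("not a directory")
        cfg = make_config(n_slices=2, mirror_dir=str(blocker / "sub"))
        engine = AcquisitionEngine(cfg, make_instrument(cfg))
        state = engine.run()
        assert state.status == "finished"
        notes = (engine.base_dir / "notifications.log").read_text()
        assert "mirror" in notes

    def test_wd_gradient_applied_per_tile(self, make_config, small_grid):
        from sbemctl.focus import fit_focus_gradient
        small_grid.gradient = fit_focus_gradient(
            [((0, 0), 7.0), ((100, 0), 7.01), ((0, 100), 7.02)])
        cfg = make_config(grids=[small_grid], n_slices=1)
        engine = AcquisitionEngine(cfg, make_instrument(cfg))
        engine.run()
        recs = {(r.row, r.col): r.wd for r in read_metadata(engine.base_dir)
                if r.grid_id >= 0}
        for (row, col), wd in recs.items():
            expected = small_grid.gradient.wd_at(small_grid.tile_center(row, col))
            assert wd == pytest.approx(expected, abs=1e-12)

    def test_periodic_autofocus_resets_working_distance(self, make_config):
        cfg = make_config(n_slices=3, autofocus_mode="periodic",
                          autofocus_interval=1, autofocus_ref_tiles={(0, 0)},
                          wd=7.005)  # start defocused
        inst = make_instrument(cfg)
        engine = AcquisitionEngine(cfg, inst)
        engine.run()
        assert inst.count_commands("AUTOFOCUS") == 3
        center = cfg.grids[0].tile_center(0, 0)
        assert engine.focus_state.wd == pytest.approx(inst.true_wd(center))
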