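import numpy as np
import pytest

from sbemctl.debris import SweepPolicy, detect_debris_quadrant
from sbemctl.errors import SbemError
from sbemctl.focus import sharpness_score
from sbemctl.geometry import Rect, estimate_calibration, sem_to_stage
from sbemctl.instrument import SemRect, SimulatorParams, VirtualInstrument
from sbemctl.protocol import (CommandMessage, InstrumentServer, ProtocolBackend,
                              command_exchange)


class TestImaging:
    def test_same_history_same_seed_bit_identical(self, calib):
        imgs = []
        for _ in range(2):
            inst = VirtualInstrument(SimulatorParams(), calib, seed=123)
            inst.cut(25.0)
            imgs.append(inst.acquire_frame((5.0, -3.0), (120, 90), 50.0, 0.8, 7.0))
        assert np.array_equal(imgs[0], imgs[1])

    def test_noise_variance_scales_inversely_with_dwell(self, calib):
        # quartering the dwell time quadruples the pixel-noise variance
        params = SimulatorParams(knife_tilt=(0.0, 0.0))
        variances = {}
        for dwell in (0.8, 0.2):
            diffs = []
            inst = VirtualInstrument(params, calib, seed=9)
            clean = inst.render_face(*np.meshgrid(
                (np.arange(64) - 31.5) * 0.01, (np.arange(64) - 31.5) * 0.01))
            for _ in range(100):
                frame = inst.acquire_frame((0.0, 0.0), (64, 64), 10.0, dwell,
                                           inst.true_wd((0.0, 0.0)))
                diffs.append((frame.astype(float) - clean).var())
            variances[dwell] = np.mean(diffs)
        assert variances[0.2] / variances[0.8] == pytest.approx(4.0, rel=0.10)

    def test_in_focus_frame_sharpness_matches_noise_free_render(self, calib):
        # sample outside the bright specimen so no gray levels clip
        inst = VirtualInstrument(SimulatorParams(knife_tilt=(0.0, 0.0)),
                                 calib, seed=4)
        sem = (70.0, 0.0)
        xs = sem[0] + (np.arange(128) - 63.5) * 0.01
        ys = sem[1] + (np.arange(96) - 47.5) * 0.01
        oracle = inst.render_face(*np.meshgrid(xs, ys))
        frame = inst.acquire_frame(sem_to_stage(sem, calib), (128, 96), 10.0,
                                   1e4, inst.true_wd(sem))
        assert sharpness_score(frame) == pytest.approx(sharpness_score(oracle),
                                                       rel=0.05)

    def test_out_of_range_target_is_stage_error(self, instrument):
        with pytest.raises(SbemError) as exc:
            instrument.acquire_frame((5000.0, 0.0), (32, 32), 10.0, 0.8, 7.0)
        assert exc.value.group == 2


class TestMicrotome:
    def test_cut_additivity(self, instrument):
        for _ in range(100):
            instrument.cut(25.0)
        assert instrument.face_z == pytest.approx(2500.0)
        assert instrument.slice_idx == 100

    def test_sweep_with_certain_removal_clears_debris(self, instrument):
        instrument.inject_debris(0, SemRect(0, 0, 5, 5), 50.0,
                                 removal_probability=1.0)
        instrument.sweep(70.0)
        assert instrument.active_debris() == []

    def test_default_policy_sweep_lowers_face_exactly_70nm(self, instrument):
        z0 = instrument.face_z
        instrument.sweep(SweepPolicy().depth)
        assert instrument.face_z - z0 == pytest.approx(70.0)

    def test_zero_removal_probability_survives_sweeps(self, instrument):
        instrument.inject_debris(0, SemRect(0, 0, 5, 5), 50.0,
                                 removal_probability=0.0)
        for _ in range(10):
            instrument.sweep(70.0)
        assert len(instrument.active_debris()) == 1


class TestDebrisCompositing:
    def test_zero_contrast_debris_is_invisible(self, quiet_instrument):
        motor = (0.0, 0.0)
        a = quiet_instrument.acquire_frame(motor, (64, 64), 100.0, 0.8, 7.0)
        quiet_instrument.inject_debris(0, SemRect(-2, -2, 4, 4), 0.0, 1.0)
        b = quiet_instrument.acquire_frame(motor, (64, 64), 100.0, 0.8, 7.0)
        assert np.array_equal(a, b)

    def test_quadrant_mean_shift_equals_contrast_noise_free(self, calib):
        # patch exactly covering the top-left quadrant of the footprint
        inst = VirtualInstrument(
            SimulatorParams(noise_scale=0.0, knife_tilt=(0.0, 0.0)),
            calib, seed=6)
        sem = (70.0, 0.0)  # outside the bright specimen: no clipping
        motor = sem_to_stage(sem, calib)
        w, h, ps = 64, 64, 0.1  # px, px, um
        prev = inst.acquire_frame(motor, (w, h), 100.0, 0.8, inst.true_wd(sem))
        inst.inject_debris(0, SemRect(sem[0] - w / 2 * ps, sem[1] - h / 2 * ps,
                                      w / 2 * ps, h / 2 * ps), 20.0, 1.0)
        curr = inst.acquire_frame(motor, (w, h), 100.0, 0.8, inst.true_wd(sem))
        report = detect_debris_quadrant(prev, curr, Rect(0, 0, w, h), 10, 10)
        assert report.per_region_diffs[0] == pytest.approx(20.0)
        assert report.per_region_diffs[1:4] == pytest.approx([0.0, 0.0, 0.0])

    def test_debris_appears_only_from_its_slice(self, quiet_instrument):
        quiet_instrument.inject_debris(2, SemRect(-2, -2, 4, 4), 30.0, 0.0)
        a = quiet_instrument.acquire_frame((0.0, 0.0), (64, 64), 100.0, 0.8, 7.0)
        quiet_instrument.cut(25.0)
        quiet_instrument.cut(25.0)
        b = quiet_instrument.acquire_frame((0.0, 0.0), (64, 64), 100.0, 0.8, 7.0)
        assert b.astype(int).mean() > a.astype(int).mean() + 3


def test_hidden_calibration_recovered_through_motor_interface(calib):
    """End-to-end: the stage only speaks motor coordinates, and calibrating
    against it recovers the hidden rotation/scale parameters."""
    inst = VirtualInstrument(SimulatorParams(), calib, seed=1)
    disps = [(20.0, 0.0), (0.0, 20.0), (15.0, 15.0)]
    pairs = [(d, inst.measure_motor_displacement(d)) for d in disps]
    est = estimate_calibration(pairs)
    assert est.angle_x == pytest.approx(calib.angle_x, abs=1e-6)
    assert est.angle_y == pytest.approx(calib.angle_y, abs=1e-6)
    assert est.scale_x == pytest.approx(calib.scale_x, abs=1e-9)
    assert est.scale_y == pytest.approx(calib.scale_y, abs=1e-9)


class TestProtocol:
    def test_message_allows_at_most_two_params(self):
        CommandMessage("CUT", (25.0,))
        CommandMessage("MOVE", (1.0, 2.0))
        with pytest.raises(SbemError) as exc:
            CommandMessage("MOVE", (1.0, 2.0, 3.0))
        assert exc.value.group == 1

    def test_cut_command_advances_face(self, instrument, tmp_path):
        server = InstrumentServer(instrument, tmp_path, poll_interval=0.02).start()
        try:
            command_exchange(tmp_path, CommandMessage("CUT", (25.0,)),
                             poll_interval=0.02)
            face = command_exchange(tmp_path, CommandMessage("GETFACE"),
                                    poll_interval=0.02)
            assert float(face[0]) == pytest.approx(25.0)
        finally:
            server.stop()

    def test_absent_instrument_times_out_as_group1(self, tmp_path):
        with pytest.raises(SbemError) as exc:
            command_exchange(tmp_path, CommandMessage("CUT", (25.0,)),
                             poll_interval=0.02, timeout=0.2)
        assert exc.value.group == 1

    def test_unknown_command_maps_to_protocol_error(self, instrument, tmp_path):
        server = InstrumentServer(instrument, tmp_path, poll_interval=0.02).start()
        try:
            with pytest.raises(SbemError) as exc:
                command_exchange(tmp_path, CommandMessage("WHAT"),
                                 poll_interval=0.02)
            assert exc.value.group == 1
        finally:
            server.stop()

    def test_backend_routes_microtome_commands_via_files(self, instrument, tmp_path):
        backend = ProtocolBackend(instrument, tmp_path, poll_interval=0.02)
        try:
            backend.cut(25.0)
            backend.sweep(70.0)
            assert instrument.face_z == pytest.approx(95.0)
            assert instrument.count_commands("CUT") == 1
            assert instrument.count_commands("SWEEP") == 1
        finally:
            backend.close()

    def test_protocol_files_removed_after_consumption(self, instrument, tmp_path):
        backend = ProtocolBackend(instrument, tmp_path, poll_interval=0.02)
        try:
            backend.cut(25.0)
        finally:
            backend.close()
        leftovers = [p.name for p in tmp_path.iterdir()]
        assert "trigger" not in leftovers and "command.in" not in leftovers
        assert "response.out" not in leftovers
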