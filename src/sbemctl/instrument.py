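"""Virtual block-face instrument: a deterministic, seedable stand-in for an
in-chamber ultramicrotome plus SEM.

The simulated sample is a procedural 3D scalar field — band-limited random
cosine waves at two spatial scales (micron-scale structure visible in
overviews, sub-100-nm structure that gives high-resolution tiles their
sharpness) — with an embedded ellipsoidal "specimen" of distinct texture
whose cross-section changes with depth, emulating an irregular biological
sample.  Imaging always reads the field at the current block-face depth
``face_z``; cutting and sweeping advance ``face_z`` (never backwards).

The focus model: each position has a true working distance
``base_wd + tilt . p + drift``; the knife tilt produces the tilted-surface
focus gradient.  Frames acquired at a different WD are Gaussian-blurred
with sigma proportional to the defocus (a physical length, so defocus
matters at tile resolution and barely at overview resolution); pixel noise
is Gaussian with
variance proportional to 1/dwell_time.  Blur/noise constants are simulator
parameters, not claims about real electron optics.

The stage exposes only **motor** coordinates; the hidden rotation/scale
calibration maps them back to the sample frame, so an engine must go
through its own :class:`~sbemctl.geometry.StageCalibration` to land where
it intends.

Everything is deterministic given (seed, full command history); the command
log is the oracle used by the engine tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (E_ACQUISITION_FAILURE, E_CUT_FAILURE, E_STAGE_RANGE,
                     E_SWEEP_FAILURE, InstrumentFault, SbemError)
from .geometry import StageCalibration, Vec2, stage_to_sem


@dataclass
class SemRect:
    """Axis-aligned rectangle in SEM-frame microns."""

    x: float
    y: float
    w: float
    h: float

    def contains_grid(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return ((X >= self.x) & (X < self.x + self.w)
                & (Y >= self.y) & (Y < self.y + self.h))


@dataclass
class DebrisPatch:
    region: SemRect
    contrast: float  # gray levels added where the patch covers the face
    removal_probability: float
    from_slice: int
    removed: bool = False


@dataclass
class SimulatorParams:
    """Tunable physics of the virtual instrument."""

    base_wd: float = 7.0               # mm, true WD at the SEM origin
    knife_tilt: Vec2 = (0.02, 0.01)    # dWD/dx, dWD/dy in mm per mm
    wd_drift_per_slice: float = 0.0    # mm added to true WD at every cut
    blur_nm_per_mm: float = 15000.0    # defocus blur sigma (nm) per mm of WD error
    noise_scale: float = 8.0           # noise std = noise_scale / sqrt(dwell_us)
    texture_contrast: float = 35.0     # gray levels around the mid-level 128
    specimen_center: Tuple[float, float, float] = (0.0, 0.0, 4000.0)  # um, um, nm
    specimen_semiaxes: Tuple[float, float, float] = (60.0, 40.0, 6000.0)  # um, um, nm
    specimen_brightness: float = 40.0  # extra gray levels inside the specimen
    motor_range_um: float = 1000.0     # reachable +- range of each motor axis
    n_coarse_waves: int = 24
    n_fine_waves: int = 16
    coarse_wavelength_um: Tuple[float, float] = (2.0, 20.0)
    fine_wavelength_um: Tuple[float, float] = (0.05, 0.4)
    z_wavelength_um: Tuple[float, float] = (2.0, 10.0)
    autofocus_residual_mm: float = 0.0  # residual error of the vendor autofocus


class VirtualInstrument:
    """In-process backend simulating stage, knife, detector and sample.

    Parameters
    ----------
    params : SimulatorParams
    calibration : StageCalibration
        The *hidden* motor-axis calibration; engines see only motor
        coordinates and must estimate this mapping themselves.
    seed : int
        Master seed for texture generation, noise, and debris removal.
    """

    def __init__(self, params: Optional[SimulatorParams] = None,
                 calibration: Optional[StageCalibration] = None,
                 seed: int = 0):
        self.params = params or SimulatorParams()
        self.calibration = calibration or StageCalibration.identity()
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self.face_z = 0.0  # nm, non-decreasing
        self.slice_idx = 0  # number of cuts performed
        self.wd_drift = 0.0  # mm
        self.debris: List[DebrisPatch] = []
        self.command_log: List[str] = []
        self._faults: Dict[str, List[int]] = {}
        self._waves = self._make_waves(np.random.default_rng(self.seed ^ 0x5EED))

    # ---------------------------------------------------------------- texture

    def _make_waves(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        p = self.params

        def bank(n: int, wl_range: Tuple[float, float]) -> np.ndarray:
            wl = rng.uniform(*wl_range, size=n)
            theta = rng.uniform(0, 2 * math.pi, size=n)
            k = 2 * math.pi / wl
            kz = 2 * math.pi / rng.uniform(*p.z_wavelength_um, size=n)
            phase = rng.uniform(0, 2 * math.pi, size=n)
            amp = rng.uniform(0.5, 1.0, size=n)
            amp /= np.sqrt((amp ** 2).sum() / 2)  # unit-RMS bank
            return np.stack([amp, k * np.cos(theta), k * np.sin(theta), kz, phase])

        return {
            "coarse": bank(p.n_coarse_waves, p.coarse_wavelength_um),
            "fine": bank(p.n_fine_waves, p.fine_wavelength_um),
            "spec": bank(p.n_fine_waves, p.fine_wavelength_um),
        }

    def _eval_bank(self, bank: np.ndarray, X: np.ndarray, Y: np.ndarray,
                   z_um: float) -> np.ndarray:
        amp, kx, ky, kz, phase = bank
        out = np.zeros_like(X)
        for i in range(amp.size):
            out += amp[i] * np.cos(kx[i] * X + ky[i] * Y + kz[i] * z_um + phase[i])
        return out

    def _specimen_mask(self, X: np.ndarray, Y: np.ndarray, z_nm: float) -> np.ndarray:
        cx, cy, cz = self.params.specimen_center
        ax, ay, az = self.params.specimen_semiaxes
        dz2 = ((z_nm - cz) / az) ** 2
        if dz2 >= 1.0:
            return np.zeros_like(X, dtype=bool)
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0 - dz2

    def render_face(self, X: np.ndarray, Y: np.ndarray,
                    z_nm: Optional[float] = None) -> np.ndarray:
        """Noise-free, blur-free gray-level field at SEM coordinates (um)."""
        p = self.params
        z = self.face_z if z_nm is None else z_nm
        z_um = z / 1000.0
        img = 128.0 + p.texture_contrast * self._eval_bank(self._waves["coarse"], X, Y, z_um)
        img += 0.5 * p.texture_contrast * self._eval_bank(self._waves["fine"], X, Y, z_um)
        mask = self._specimen_mask(X, Y, z)
        if mask.any():
            spec = self._eval_bank(self._waves["spec"], X, Y, z_um)
            img = np.where(mask, img + p.specimen_brightness
                           + 0.5 * p.texture_contrast * spec, img)
        return img

    # ----------------------------------------------------------------- faults

    def inject_fault(self, op: str, count: int = 1) -> None:
        """Make the next ``count`` calls of ``op`` fail (for retry tests).

        ops: 'acquire', 'cut', 'sweep', 'blank' (acquire returns a blank
        frame instead of raising).
        """
        if count < 1:
            raise ValueError("fault count must be >= 1")
        self._faults.setdefault(op, []).append(count)

    def _consume_fault(self, op: str) -> bool:
        counts = self._faults.get(op)
        if counts and counts[0] > 0:
            counts[0] -= 1
            if counts[0] == 0:
                counts.pop(0)
            return True
        return False

    # ------------------------------------------------------------------ stage

    def _motor_to_sem(self, motor: Vec2) -> Vec2:
        return stage_to_sem(motor, self.calibration)

    def measure_motor_displacement(self, sem_disp: Vec2) -> Vec2:
        """Stage-readout displacement for a commanded SEM displacement
        (the measurement primitive behind stage calibration)."""
        m = self.calibration.matrix() @ np.asarray(sem_disp, dtype=float)
        self.command_log.append(f"CALMOVE {sem_disp[0]:.6f} {sem_disp[1]:.6f}")
        return (float(m[0]), float(m[1]))

    def true_wd(self, sem_pos: Vec2) -> float:
        tx, ty = self.params.knife_tilt
        return (self.params.base_wd + tx * sem_pos[0] / 1000.0
                + ty * sem_pos[1] / 1000.0 + self.wd_drift)

    def vendor_autofocus(self, center_motor: Vec2) -> float:
        """Oracle stand-in for the vendor autofocus: returns the true WD at
        the position plus a configurable residual error."""
        sem = self._motor_to_sem(center_motor)
        self.command_log.append(f"AUTOFOCUS {center_motor[0]:.3f} {center_motor[1]:.3f}")
        return self.true_wd(sem) + self.params.autofocus_residual_mm

    # ---------------------------------------------------------------- imaging

    def acquire_frame(self, center_motor: Vec2, frame: Tuple[int, int],
                      pixel_size: float, dwell: float, wd: float) -> np.ndarray:
        """Acquire one frame centered at the given motor position.

        frame = (width, height) px; pixel_size in nm; dwell in us; wd in mm.
        Returns an 8-bit grayscale image.
        """
        rng_limit = self.params.motor_range_um
        if abs(center_motor[0]) > rng_limit or abs(center_motor[1]) > rng_limit:
            raise SbemError(E_STAGE_RANGE,
                            f"motor target {center_motor} outside +-{rng_limit} um")
        w, h = frame
        self.command_log.append(
            f"ACQUIRE {center_motor[0]:.3f} {center_motor[1]:.3f} {w} {h} "
            f"{pixel_size:.2f} {dwell:.3f} {wd:.6f}")
        if self._consume_fault("acquire"):
            raise InstrumentFault(E_ACQUISITION_FAILURE, "simulated acquisition failure")
        if self._consume_fault("blank"):
            return np.zeros((h, w), dtype=np.uint8)

        cx, cy = self._motor_to_sem(center_motor)
        ps = pixel_size / 1000.0  # um
        xs = cx + (np.arange(w) - (w - 1) / 2.0) * ps
        ys = cy + (np.arange(h) - (h - 1) / 2.0) * ps
        X, Y = np.meshgrid(xs, ys)
        img = self.render_face(X, Y)

        for patch in self.debris:
            if patch.removed or self.slice_idx < patch.from_slice:
                continue
            mask = patch.region.contains_grid(X, Y)
            if mask.any():
                img = np.where(mask, img + patch.contrast, img)

        defocus = abs(wd - self.true_wd((cx, cy)))
        # defocus blur is a physical length: fine at high magnification,
        # negligible at overview pixel sizes
        sigma = defocus * self.params.blur_nm_per_mm / pixel_size
        if sigma > 0.01:
            img = gaussian_filter(img, sigma=min(sigma, 50.0), mode="nearest")
        if self.params.noise_scale > 0 and dwell > 0:
            img = img + self._rng.normal(
                0.0, self.params.noise_scale / math.sqrt(dwell), size=img.shape)
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # -------------------------------------------------------------- microtome

    def cut(self, thickness: float) -> None:
        """Cut one slice: advance the block face by ``thickness`` nm."""
        if thickness <= 0:
            raise ValueError("cut thickness must be > 0")
        self.command_log.append(f"CUT {thickness:.2f}")
        if self._consume_fault("cut"):
            raise InstrumentFault(E_CUT_FAILURE, "simulated cut failure")
        self.face_z += float(thickness)
        self.slice_idx += 1
        self.wd_drift += self.params.wd_drift_per_slice

    def sweep(self, depth: float) -> None:
        """Lower the sample by ``depth`` nm and sweep the knife across the
        face; each active debris patch is removed independently with its
        removal probability."""
        if depth <= 0:
            raise ValueError("sweep depth must be > 0")
        self.command_log.append(f"SWEEP {depth:.2f}")
        if self._consume_fault("sweep"):
            raise InstrumentFault(E_SWEEP_FAILURE, "simulated sweep failure")
        self.face_z += float(depth)
        for patch in self.debris:
            if patch.removed or self.slice_idx < patch.from_slice:
                continue
            if self._rng.random() < patch.removal_probability:
                patch.removed = True

    def inject_debris(self, slice_idx: int, region: SemRect, contrast: float,
                      removal_probability: float = 1.0) -> None:
        if not 0.0 <= removal_probability <= 1.0:
            raise ValueError("removal_probability must be in [0, 1]")
        self.debris.append(DebrisPatch(region, contrast, removal_probability,
                                       from_slice=slice_idx))

    # ------------------------------------------------------------------ misc

    def active_debris(self) -> List[DebrisPatch]:
        return [p for p in self.debris
                if not p.removed and self.slice_idx >= p.from_slice]

    def count_commands(self, prefix: str) -> int:
        return sum(1 for c in self.command_log if c.startswith(prefix))
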