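"""Error taxonomy for the acquisition engine.

Error codes have three digits and are grouped by the first digit:

1. communication with the microtome control host (trigger-file protocol)
2. microtome / stage hardware
3. SEM / vendor acquisition software
4. I/O (disk, network drives)
5. acquisition process and image inspection
6. user-defined checks

Unresolvable errors pause the acquisition; the engine maps every failure
through one of these codes so logs and pause reasons are machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GROUP_NAMES = {
    1: "communication",
    2: "microtome/stage",
    3: "SEM",
    4: "I/O",
    5: "acquisition/inspection",
    6: "user-defined",
}

# Communication (1xx)
E_PROTOCOL_TIMEOUT = 101
E_PROTOCOL_VIOLATION = 102
# Microtome / stage (2xx)
E_STAGE_MOVE = 201
E_CUT_FAILURE = 202
E_SWEEP_FAILURE = 203
E_STAGE_RANGE = 204
E_CALIBRATION = 205
# SEM (3xx)
E_ACQUISITION_FAILURE = 301
# I/O (4xx)
E_WRITE_FAILURE = 401
E_MIRROR_UNAVAILABLE = 402
E_UNREADABLE_FILE = 403
# Acquisition / inspection (5xx)
E_DIMENSION_MISMATCH = 501
E_UNIFORM_IMAGE = 502
E_RANGE_VIOLATION = 503
E_TILE_DELTA = 504
E_DEBRIS_UNRESOLVED = 505
E_CONFIG = 506
E_DEGENERATE_INPUT = 507
# User-defined (6xx)
E_USER_CHECK = 601


@dataclass
class ErrorCode:
    """A three-digit error code with its derived group."""

    code: int
    message: str = ""
    group: int = field(init=False)

    def __post_init__(self) -> None:
        if not 100 <= self.code <= 699:
            raise ValueError(f"error code must be three digits in 100-699, got {self.code}")
        self.group = self.code // 100

    @property
    def group_name(self) -> str:
        return GROUP_NAMES[self.group]

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"E{self.code} ({self.group_name}): {self.message}"


class SbemError(Exception):
    """Exception carrying an :class:`ErrorCode`."""

    def __init__(self, code: int, message: str = ""):
        self.error = ErrorCode(code, message)
        super().__init__(str(self.error))

    @property
    def code(self) -> int:
        return self.error.code

    @property
    def group(self) -> int:
        return self.error.group


class InstrumentFault(SbemError):
    """A (possibly transient) hardware/software fault raised by a backend.

    Faults are retried by the engine; persistent faults pause the run.
    """
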