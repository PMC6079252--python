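"""Trigger-file command exchange with the microtome control host.

The engine and the microtome controller share a directory.  To issue a
command, the engine writes an input file holding one command word and up to
two parameters, then creates an empty trigger file.  The controller polls
for the trigger file at 0.1-s intervals, consumes both files, executes the
command, and writes a one-line response file, which the engine picks up and
removes.  This mirrors how stage/knife commands are exchanged with the
proprietary microtome software through its internal scripting language;
image acquisition uses the direct (in-process) path, as on a real system
where frames flow through the vendor acquisition API instead.

Protocol files: ``command.in`` (``CMD [p1 [p2]]``), ``trigger`` (empty),
``response.out`` (``OK [values...]`` or ``ERR code message``).
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .errors import (E_PROTOCOL_TIMEOUT, E_PROTOCOL_VIOLATION, SbemError)
from .geometry import Vec2
from .instrument import VirtualInstrument

POLL_INTERVAL_S = 0.1  # how often the controller side checks for a trigger file

COMMAND_FILE = "command.in"
TRIGGER_FILE = "trigger"
RESPONSE_FILE = "response.out"


@dataclass
class CommandMessage:
    """One command with up to two parameters."""

    command: str
    params: Tuple[Union[float, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.params) > 2:
            raise SbemError(E_PROTOCOL_VIOLATION,
                            f"at most two parameters allowed, got {len(self.params)}")
        if not self.command or any(ch.isspace() for ch in self.command):
            raise SbemError(E_PROTOCOL_VIOLATION, "command must be a single word")

    def serialize(self) -> str:
        return " ".join([self.command] + [str(p) for p in self.params])


def command_exchange(shared_dir: Union[str, Path], msg: CommandMessage,
                     poll_interval: float = POLL_INTERVAL_S,
                     timeout: float = 5.0) -> List[str]:
    """Send one command through the shared directory and wait for the reply.

    Returns the whitespace-split response values; raises a group-1 error on
    timeout and maps ``ERR`` responses back to :class:`SbemError`.
    """
    d = Path(shared_dir)
    (d / COMMAND_FILE).write_text(msg.serialize() + "\n")
    (d / TRIGGER_FILE).touch()
    deadline = time.monotonic() + timeout
    resp = d / RESPONSE_FILE
    while time.monotonic() < deadline:
        if resp.exists():
            line = resp.read_text().strip()
            resp.unlink()
            parts = line.split()
            if parts and parts[0] == "ERR":
                code = int(parts[1]) if len(parts) > 1 else E_PROTOCOL_VIOLATION
                raise SbemError(code, " ".join(parts[2:]))
            return parts[1:] if parts and parts[0] == "OK" else parts
        time.sleep(poll_interval)
    raise SbemError(E_PROTOCOL_TIMEOUT,
                    f"no response to '{msg.command}' within {timeout} s")


class InstrumentServer:
    """Controller-side poll loop executing commands on a VirtualInstrument.

    Runs in a daemon thread; supported commands: ``CUT t``, ``SWEEP d``,
    ``GETFACE``, ``GETSLICE``, ``STOP``.
    """

    def __init__(self, instrument: VirtualInstrument, shared_dir: Union[str, Path],
                 poll_interval: float = POLL_INTERVAL_S):
        self.instrument = instrument
        self.dir = Path(shared_dir)
        self.poll_interval = poll_interval
        self._stop = threading.Event()
        self._thread: Optional[threading.Thread] = None

    def start(self) -> "InstrumentServer":
        self.dir.mkdir(parents=True, exist_ok=True)
        self._thread = threading.Thread(target=self._loop, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._stop.set()
        if self._thread is not None:
            self._thread.join(timeout=5.0)

    def _loop(self) -> None:
        trigger = self.dir / TRIGGER_FILE
        cmdfile = self.dir / COMMAND_FILE
        while not self._stop.is_set():
            if not trigger.exists():
                self._stop.wait(self.poll_interval)
                continue
            try:
                line = cmdfile.read_text().strip()
            except OSError:
                line = ""
            for f in (trigger, cmdfile):
                try:
                    f.unlink()
                except OSError:
                    pass
            self._respond(self._execute(line.split()))

    def _execute(self, parts: Sequence[str]) -> str:
        if not parts:
            return f"ERR {E_PROTOCOL_VIOLATION} empty command"
        if len(parts) > 3:
            return f"ERR {E_PROTOCOL_VIOLATION} too many parameters"
        cmd, args = parts[0].upper(), parts[1:]
        try:
            if cmd == "CUT":
                self.instrument.cut(float(args[0]))
                return "OK"
            if cmd == "SWEEP":
                self.instrument.sweep(float(args[0]))
                return "OK"
            if cmd == "GETFACE":
                return f"OK {self.instrument.face_z:.3f}"
            if cmd == "GETSLICE":
                return f"OK {self.instrument.slice_idx}"
            if cmd == "STOP":
                self._stop.set()
                return "OK"
            return f"ERR {E_PROTOCOL_VIOLATION} unknown command {cmd}"
        except SbemError as exc:
            return f"ERR {exc.code} {exc.error.message}"
        except (ValueError, IndexError) as exc:
            return f"ERR {E_PROTOCOL_VIOLATION} {exc}"

    def _respond(self, line: str) -> None:
        tmp = self.dir / (RESPONSE_FILE + ".tmp")
        tmp.write_text(line + "\n")
        tmp.rename(self.dir / RESPONSE_FILE)


class ProtocolBackend:
    """Backend routing microtome commands through the trigger-file protocol.

    Wraps a :class:`VirtualInstrument`: ``cut``/``sweep`` travel through the
    shared-directory exchange (with the 0.1-s poll loop on the controller
    side), while imaging and stage measurements use the direct path.
    """

    def __init__(self, instrument: VirtualInstrument, shared_dir: Union[str, Path],
                 poll_interval: float = POLL_INTERVAL_S):
        self.instrument = instrument
        self.dir = Path(shared_dir)
        self.server = InstrumentServer(instrument, shared_dir, poll_interval).start()

    # microtome commands via the file protocol
    def cut(self, thickness: float) -> None:
        command_exchange(self.dir, CommandMessage("CUT", (thickness,)))

    def sweep(self, depth: float) -> None:
        command_exchange(self.dir, CommandMessage("SWEEP", (depth,)))

    # direct paths
    def acquire_frame(self, *args, **kwargs):
        return self.instrument.acquire_frame(*args, **kwargs)

    def measure_motor_displacement(self, sem_disp: Vec2) -> Vec2:
        return self.instrument.measure_motor_displacement(sem_disp)

    def vendor_autofocus(self, center_motor: Vec2) -> float:
        return self.instrument.vendor_autofocus(center_motor)

    def inject_debris(self, *args, **kwargs) -> None:
        self.instrument.inject_debris(*args, **kwargs)

    def inject_fault(self, *args, **kwargs) -> None:
        self.instrument.inject_fault(*args, **kwargs)

    @property
    def command_log(self):
        return self.instrument.command_log

    @property
    def face_z(self):
        return self.instrument.face_z

    @property
    def slice_idx(self):
        return self.instrument.slice_idx

    def close(self) -> None:
        self.server.stop()
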