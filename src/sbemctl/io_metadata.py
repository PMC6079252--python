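"""Image and metadata persistence.

Tiles are written as uncompressed grayscale TIFFs under a fixed,
parseable naming scheme::

    <base>/tiles/g{GGGG}/t{RRRR}x{CCCC}/{stack}_g{GGGG}_t{RRRR}x{CCCC}_s{SSSSS}.tif
    <base>/overviews/ov{OOOO}/{stack}_ov{OOOO}_s{SSSSS}.tif

(zero-padded indices; the template is isolated behind one format/parse pair
so it can be swapped).  One metadata record per written file is appended to
a line-delimited JSON stream, so a crashed run loses at most one line.  A
mirror drive can be kept in sync during the acquisition as a backup and
post-processing source; the primary store stays authoritative and mirror
failures never pause a run.  Records can be exported as a TrakEM2 import
text file (path, x offset px, y offset px, section index) for stitching and
alignment pipelines.
"""

from __future__ import annotations

import hashlib
import json
import re
import shutil
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

from .errors import E_CONFIG, E_WRITE_FAILURE, SbemError
from .geometry import Vec2


@dataclass
class TileRecord:
    """Metadata for one written tile or overview image."""

    path: str  # relative to base_dir
    grid_id: int
    row: int
    col: int
    slice_idx: int
    stage_pos: Vec2  # motor um
    sem_pos: Vec2  # SEM um
    pixel_size: float  # nm
    wd: float  # mm
    timestamp: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "TileRecord":
        d = json.loads(line)
        d["stage_pos"] = tuple(d["stage_pos"])
        d["sem_pos"] = tuple(d["sem_pos"])
        return cls(**d)


def tile_relpath(stack: str, grid_id: int, row: int, col: int, slice_idx: int) -> str:
    """Relative path of a tile under the naming scheme."""
    g = f"g{grid_id:04d}"
    t = f"t{row:04d}x{col:04d}"
    return f"tiles/{g}/{t}/{stack}_{g}_{t}_s{slice_idx:05d}.tif"


def overview_relpath(stack: str, ov_id: int, slice_idx: int) -> str:
    o = f"ov{ov_id:04d}"
    return f"overviews/{o}/{stack}_{o}_s{slice_idx:05d}.tif"


_TILE_RE = re.compile(
    r"tiles/g(\d{4})/t(\d{4})x(\d{4})/(?P<stack>.+)_g\1_t\2x\3_s(\d{5})\.tif$")


def parse_tile_relpath(relpath: str) -> Tuple[str, int, int, int, int]:
    """Inverse of :func:`tile_relpath`: (stack, grid, row, col, slice)."""
    m = _TILE_RE.match(str(relpath).replace("\\", "/"))
    if m is None:
        raise ValueError(f"path does not follow the tile naming scheme: {relpath}")
    g, r, c, s = m.group(1), m.group(2), m.group(3), m.group(5)
    return m.group("stack"), int(g), int(r), int(c), int(s)


def write_tile(img: np.ndarray, record: TileRecord, base_dir: Union[str, Path]) -> Path:
    """Write one image and append its metadata record.

    The TIFF is grayscale, uncompressed (8-bit by default, 16-bit images
    pass through).  Returns the absolute path written.
    """
    base = Path(base_dir)
    if not base.exists():
        raise SbemError(E_WRITE_FAILURE, f"base directory does not exist: {base}")
    path = base / record.path
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), np.asarray(img), photometric="minisblack",
                         compression=None)
    except OSError as exc:
        raise SbemError(E_WRITE_FAILURE, f"cannot write {path}: {exc}") from exc
    if record.timestamp == 0.0:
        record.timestamp = time.time()
    with open(base / "metadata.jsonl", "a") as fh:
        fh.write(record.to_json() + "\n")
    return path


def read_metadata(base_dir: Union[str, Path]) -> List[TileRecord]:
    path = Path(base_dir) / "metadata.jsonl"
    if not path.exists():
        return []
    return [TileRecord.from_json(line)
            for line in path.read_text().splitlines() if line.strip()]


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def mirror_sync(primary_dir: Union[str, Path], mirror_dir: Union[str, Path],
                pending: Sequence[Union[str, Path]],
                warn=None) -> List[str]:
    """Replicate pending files (paths relative to the primary) onto the
    mirror drive.

    A file counts as synced only after its size and checksum match.  Mirror
    failures are reported through ``warn`` and skipped — the primary store
    remains authoritative and the acquisition continues.
    """
    primary = Path(primary_dir)
    mirror = Path(mirror_dir)
    synced: List[str] = []
    for rel in pending:
        src = primary / rel
        dst = mirror / rel
        try:
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.copy2(src, dst)
            if (dst.stat().st_size == src.stat().st_size
                    and file_checksum(dst) == file_checksum(src)):
                synced.append(str(rel))
            elif warn is not None:
                warn(f"mirror checksum mismatch for {rel}")
        except OSError as exc:
            if warn is not None:
                warn(f"mirror unavailable for {rel}: {exc}")
    return synced


def export_trakem2(records: Iterable[TileRecord], slice_thickness: float,
                   pixel_size: Optional[float] = None) -> str:
    """Render records as a TrakEM2 import text file.

    One line per tile: image path, x offset, y offset (pixels, anchored at
    the dataset minimum SEM position), and section index, tab-separated and
    ordered by (slice, grid, row, col).  All records must share one pixel
    size; export per grid when resolutions differ.
    """
    recs = sorted(records, key=lambda r: (r.slice_idx, r.grid_id, r.row, r.col))
    if not recs:
        raise SbemError(E_CONFIG, "no records to export")
    sizes = {r.pixel_size for r in recs}
    if pixel_size is None:
        if len(sizes) > 1:
            raise SbemError(E_CONFIG,
                            f"mixed pixel sizes {sorted(sizes)}; export per grid")
        pixel_size = sizes.pop()
    min_x = min(r.sem_pos[0] for r in recs)
    min_y = min(r.sem_pos[1] for r in recs)
    lines = []
    for r in recs:
        # um -> px: 1000 nm per um over the pixel size in nm
        x_px = (r.sem_pos[0] - min_x) * 1000.0 / pixel_size
        y_px = (r.sem_pos[1] - min_y) * 1000.0 / pixel_size
        lines.append(f"{r.path}\t{x_px:.1f}\t{y_px:.1f}\t{r.slice_idx}")
    return "\n".join(lines) + "\n"
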