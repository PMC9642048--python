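"""File I/O: MRC images, pick coordinate STAR files, particle STAR files.

Two STAR dialects are produced, both single ``loop_`` tables:

* pick files (manual-picking dialect): ``_rlnCoordinateX``/``_rlnCoordinateY``
  where consecutive row pairs are the (start, end) of one filament — the
  format consumed directly by segment-extraction jobs;
* particle files: per-segment coordinates with helical tube id, tilt and psi
  angle priors and helical track length, the minimal column set a downstream
  helical extractor needs.

Coordinates are written 0-based, pixel-centre, in original-micrograph
pixels.  This is stated here prominently because downstream consumers
disagree on conventions.  MRC I/O follows MRC2014 (modes 0/1/2/6); the grid
is returned with array row -> image y, column -> x.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import mrcfile
import numpy as np

from .helix_geometry import FilamentTrace, ParticleRecord

__all__ = [
    "MicrographImage",
    "MrcFormatError",
    "MalformedHeaderError",
    "UnsupportedModeError",
    "TruncatedDataError",
    "StarFormatError",
    "read_mrc",
    "write_mrc",
    "write_pick_star",
    "read_pick_star",
    "write_particles_star",
    "read_particles_star",
    "parse_star_loop",
]

PICK_COLUMNS = ("_rlnCoordinateX", "_rlnCoordinateY")
PARTICLE_COLUMNS = (
    "_rlnMicrographName",
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnHelicalTubeID",
    "_rlnAngleTiltPrior",
    "_rlnAnglePsiPrior",
    "_rlnHelicalTrackLengthAngst",
)

_MRC_MODE_DTYPES = {0: 1, 1: 2, 2: 4, 6: 2}  # mode -> bytes per voxel
_MRC_HEADER_BYTES = 1024


class MrcFormatError(Exception):
    """Base error for unreadable MRC files."""


class MalformedHeaderError(MrcFormatError):
    pass


class UnsupportedModeError(MrcFormatError):
    pass


class TruncatedDataError(MrcFormatError):
    pass


class StarFormatError(Exception):
    """Raised for STAR files that do not match the expected dialect."""


@dataclass
class MicrographImage:
    """A 2-D micrograph (or score map) with its pixel size in Angstrom."""

    values: np.ndarray
    pixel_size_A: float = 1.0
    source_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"micrograph must be 2-D, got shape {self.values.shape}")
        if self.pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be positive, got {self.pixel_size_A}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def _validate_mrc_header(path: Path) -> None:
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise MalformedHeaderError(
            f"{path}: file shorter than the 1024-byte MRC header"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if nx < 1 or ny < 1 or nz < 1 or nx > 1 << 20 or ny > 1 << 20:
        raise MalformedHeaderError(
            f"{path}: malformed header (dimensions {nx} x {ny} x {nz})"
        )
    if mode not in _MRC_MODE_DTYPES:
        raise UnsupportedModeError(f"{path}: unsupported MRC mode {mode}")
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if nsymbt < 0:
        raise MalformedHeaderError(f"{path}: negative extended header size {nsymbt}")
    expected = _MRC_HEADER_BYTES + nsymbt + nx * ny * nz * _MRC_MODE_DTYPES[mode]
    if len(raw) < expected:
        raise TruncatedDataError(
            f"{path}: file holds {len(raw)} bytes, header promises {expected}"
        )


def read_mrc(path, default_pixel_size_A: float = 1.0) -> MicrographImage:
    """Read a 2-D MRC image (modes 0/1/2/6).

    The pixel size comes from the header voxel size; a zero/unset voxel size
    falls back to ``default_pixel_size_A``.  3-D files with a single section
    are squeezed to 2-D.  Raises :class:`MalformedHeaderError`,
    :class:`UnsupportedModeError` or :class:`TruncatedDataError` for broken
    files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_mrc_header(path)
    with mrcfile.open(path, mode="r", permissive=False) as mrc:
        data = np.asarray(mrc.data, dtype=np.float64)
        vx = float(mrc.voxel_size.x)
    if data.ndim == 3:
        if data.shape[0] != 1:
            raise MrcFormatError(f"{path}: expected a single 2-D image, got a stack")
        data = data[0]
    pixel = vx if vx > 0 else default_pixel_size_A
    return MicrographImage(values=data, pixel_size_A=pixel, source_name=path.name)


def write_mrc(image: MicrographImage, path) -> None:
    """Write a 2-D image as MRC mode 2 (float32) with its pixel size."""
    path = Path(path)
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(image.values.astype(np.float32))
        mrc.voxel_size = image.pixel_size_A


# ---------------------------------------------------------------------------
# STAR files


def parse_star_loop(path) -> Tuple[List[str], List[List[str]]]:
    """Parse the first loop_ block of a STAR file.

    Returns (column names, rows of whitespace-split tokens).  Comments and
    the data_ block name line are skipped.  This intentionally supports only
    the single-loop dialect this package writes and reads.
    """
    columns: List[str] = []
    rows: List[List[str]] = []
    in_loop = False
    in_body = False
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_"):
            continue
        if stripped == "loop_":
            if in_body:
                break  # second loop: out of scope
            in_loop = True
            continue
        if in_loop and stripped.startswith("_"):
            columns.append(stripped.split()[0])
            continue
        if in_loop and columns:
            in_body = True
            tokens = stripped.split()
            if len(tokens) != len(columns):
                raise StarFormatError(
                    f"{path}: row has {len(tokens)} tokens for {len(columns)} columns"
                )
            rows.append(tokens)
    if not columns:
        raise StarFormatError(f"{path}: no loop_ block found")
    return columns, rows


def write_pick_star(traces: Sequence[FilamentTrace], path) -> None:
    """Write filament start-end pairs in the manual-picking STAR dialect.

    Traces are emitted in tube_id order, two rows per trace (start, then
    end), numbers with 6 decimals.  An empty trace list yields a valid,
    header-only file.
    """
    for t in traces:
        if t.length_px <= 0:
            raise ValueError(f"degenerate zero-length trace (tube {t.tube_id})")
    lines = ["", "data_", "", "loop_"]
    lines += [f"{name} #{i}" for i, name in enumerate(PICK_COLUMNS, start=1)]
    for t in sorted(traces, key=lambda t: t.tube_id):
        lines.append(f"{t.x_start:12.6f} {t.y_start:12.6f}")
        lines.append(f"{t.x_end:12.6f} {t.y_end:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pick_star(path) -> List[FilamentTrace]:
    """Read start-end coordinate pairs; consecutive row pairs become traces
    with tube_ids assigned 1..n in file order."""
    columns, rows = parse_star_loop(path)
    try:
        ix = columns.index("_rlnCoordinateX")
        iy = columns.index("_rlnCoordinateY")
    except ValueError as exc:
        raise StarFormatError(f"{path}: missing coordinate columns") from exc
    if len(rows) % 2 != 0:
        raise StarFormatError(
            f"{path}: unpaired coordinate (odd row count {len(rows)})"
        )
    traces = []
    for k in range(0, len(rows), 2):
        x1, y1 = float(rows[k][ix]), float(rows[k][iy])
        x2, y2 = float(rows[k + 1][ix]), float(rows[k + 1][iy])
        traces.append(
            FilamentTrace(x_start=x1, y_start=y1, x_end=x2, y_end=y2,
                          tube_id=k // 2 + 1)
        )
    return traces


def write_particles_star(
    records: Sequence[ParticleRecord], micrograph_name: str, path
) -> None:
    """Write per-segment records with helical priors.

    Columns: micrograph name, x, y, helical tube id, tilt prior (90 for
    in-plane filaments), psi prior (degrees, in (-180, 180]), helical track
    length in Angstrom.
    """
    for r in records:
        if not (-180.0 < r.psi_prior_deg <= 180.0):
            raise ValueError(
                f"psi prior {r.psi_prior_deg} outside (-180, 180] "
                f"(tube {r.tube_id})"
            )
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"{name} #{i}" for i, name in enumerate(PARTICLE_COLUMNS, start=1)]
    for r in records:
        lines.append(
            f"{micrograph_name} {r.x:12.6f} {r.y:12.6f} {r.tube_id:6d} "
            f"{r.tilt_prior_deg:10.6f} {r.psi_prior_deg:11.6f} "
            f"{r.track_length_A:12.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_particles_star(path) -> Tuple[str, List[ParticleRecord]]:
    """Read a particle STAR written by :func:`write_particles_star`.

    Extra columns are ignored.  Returns (micrograph name of the first row,
    records).
    """
    columns, rows = parse_star_loop(path)
    idx = {}
    for name in PARTICLE_COLUMNS:
        try:
            idx[name] = columns.index(name)
        except ValueError as exc:
            raise StarFormatError(f"{path}: missing column {name}") from exc
    records = []
    mic_name = ""
    for row in rows:
        mic_name = mic_name or row[idx["_rlnMicrographName"]]
        records.append(
            ParticleRecord(
                x=float(row[idx["_rlnCoordinateX"]]),
                y=float(row[idx["_rlnCoordinateY"]]),
                tube_id=int(row[idx["_rlnHelicalTubeID"]]),
                psi_prior_deg=float(row[idx["_rlnAnglePsiPrior"]]),
                tilt_prior_deg=float(row[idx["_rlnAngleTiltPrior"]]),
                track_length_A=float(row[idx["_rlnHelicalTrackLengthAngst"]]),
            )
        )
    return mic_name, records
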