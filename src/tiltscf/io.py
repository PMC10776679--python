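"""Readers and writers: STAR particle tables, 3-column Euler text, MRC2014.

Angles in all file formats are degrees.  The STAR reader handles both the
legacy single-table layout and the RELION-3.1 optics-group layout by picking
the loop that carries the three angle columns (``_rlnAngleRot``,
``_rlnAngleTilt``, ``_rlnAnglePsi``); row order is preserved and no rows are
silently dropped.  The MRC codec implements the MRC2014 spec directly
(1024-byte header, mode-2 float32 data, voxel size from the cell
dimensions).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .geometry import OrientationSet
from .fsc import VolumeGrid

__all__ = [
    "read_star_orientations",
    "write_star_orientations",
    "read_euler3",
    "write_euler3",
    "read_mrc",
    "write_mrc",
]

ANGLE_COLUMNS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")


class StarParseError(ValueError):
    pass


def _parse_star_loops(lines: list[str]):
    """Yield (column_names, rows, first_data_lineno) for every loop block."""
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            i += 1
            cols = []
            while i < n:
                s = lines[i].strip()
                if s.startswith("_"):
                    cols.append(s.split()[0])
                    i += 1
                else:
                    break
            rows = []
            first_data = i + 1
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("data_", "loop_", "#")):
                    break
                fields = s.split()
                if len(fields) != len(cols):
                    raise StarParseError(
                        f"line {i + 1}: expected {len(cols)} fields "
                        f"({len(cols)} columns declared), got {len(fields)}"
                    )
                rows.append(fields)
                i += 1
            yield cols, rows, first_data
        else:
            i += 1


def read_star_orientations(path) -> OrientationSet:
    """Orientation angles from a STAR particle table, in file order."""
    path = Path(path)
    lines = path.read_text().splitlines()
    loops = list(_parse_star_loops(lines))
    if not loops:
        raise StarParseError(f"{path}: no loop_ block found")
    for cols, rows, _ in loops:
        names = {c.split("#")[0]: j for j, c in enumerate(cols)}
        if all(c in names for c in ANGLE_COLUMNS):
            if not rows:
                raise StarParseError(f"{path}: particle table has no rows")
            idx = [names[c] for c in ANGLE_COLUMNS]
            try:
                angles = np.array(
                    [[float(r[j]) for j in idx] for r in rows], dtype=float)
            except ValueError as exc:
                raise StarParseError(f"{path}: non-numeric angle value: {exc}")
            return OrientationSet(angles, label=str(path)).normalized()
    # no loop had all three: report which are missing from the best candidate
    best = max(loops, key=lambda t: sum(c in dict.fromkeys(t[0]) for c in ANGLE_COLUMNS))
    present = {c.split("#")[0] for c in best[0]}
    missing = [c for c in ANGLE_COLUMNS if c not in present]
    raise StarParseError(f"{path}: missing angle column(s): {', '.join(missing)}")


def write_star_orientations(path, orients: OrientationSet) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\ndata_particles\n\nloop_\n")
        for j, c in enumerate(ANGLE_COLUMNS, start=1):
            fh.write(f"{c} #{j}\n")
        for rot, tilt, psi in orients.angles:
            fh.write(f"{rot:12.6f} {tilt:12.6f} {psi:12.6f}\n")


def read_euler3(path) -> OrientationSet:
    """Whitespace-delimited rot/tilt/psi text, '#' comments ignored."""
    path = Path(path)
    angles = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}, row {lineno}: expected 3 columns, got {len(fields)}")
            try:
                angles.append([float(x) for x in fields])
            except ValueError:
                raise ValueError(f"{path}, row {lineno}: non-numeric value")
    if not angles:
        raise ValueError(f"{path}: no orientation rows found")
    return OrientationSet(np.array(angles), label=str(path))


def write_euler3(path, orients: OrientationSet) -> None:
    header = f"rot tilt psi (degrees), {len(orients)} projections"
    if orients.label:
        header += f", source: {orients.label}"
    if orients.seed is not None:
        header += f", seed: {orients.seed}"
    np.savetxt(path, orients.angles, fmt="%12.6f", header=header)


# ---------------------------------------------------------------------------
# MRC2014

_MRC_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
    12: np.dtype(np.float16),
}


def read_mrc(path, require_cubic: bool = False) -> VolumeGrid:
    """Read an MRC2014 volume; voxel size from cell / grid dimensions."""
    path = Path(path)
    with path.open("rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        cella = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if mode not in _MRC_MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if nsymbt:
            fh.read(nsymbt)
        dtype = _MRC_MODE_DTYPES[mode]
        data = np.frombuffer(fh.read(nx * ny * nz * dtype.itemsize), dtype=dtype)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data section")
    data = data.reshape(nz, ny, nx).astype(np.float32)
    if require_cubic and not (nx == ny == nz):
        raise ValueError(
            f"{path}: volume must be cubic for FSC, got shape ({nz}, {ny}, {nx})")
    voxel = cella[0] / nx if cella[0] > 0 else 1.0
    return VolumeGrid(data, voxel_size=float(voxel))


def write_mrc(path, volume: VolumeGrid) -> None:
    """Write an MRC2014 mode-2 (float32) volume."""
    data = np.ascontiguousarray(volume.data, dtype=np.float32)
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)                  # mx my mz
    struct.pack_into("<3f", header, 40,
                     nx * volume.voxel_size, ny * volume.voxel_size,
                     nz * volume.voxel_size)                          # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)             # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)                      # mapc/r/s
    struct.pack_into("<3f", header, 76, float(data.min()),
                     float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 108, 20140)                        # nversion
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                             # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    with Path(path).open("wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
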