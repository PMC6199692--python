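"""Plain-text geometry I/O: XYZ, the package restart format, AMBER rst7.

Three formats are supported, all ASCII:

* standard (multi-frame) XYZ in angstrom; the comment line of frames written
  by this package carries ``time_fs=... stage=...`` key/value pairs;
* the documented restart format (positions *and* velocities)::

      PSRESTART 1
      <natoms> <time_fs> <stage>
      <symbol> <x> <y> <z> <vx> <vy> <vz>      # A and A/fs, one line per atom

* AMBER ASCII restart (rst7; read-only): title line, natoms (+ optional
  time), coordinates in 6F12.7, then velocities in AMBER velocity units
  (A per 1/20.455 ps), converted to A/fs on read.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .system import Snapshot

#: AMBER velocity unit: multiply rst7 velocities by this to get A/fs
AMBER_VEL_TO_A_FS = 20.455 / 1000.0

RESTART_MAGIC = "PSRESTART"


def write_xyz(path, symbols, frames, comments: Iterable[str] | None = None) -> None:
    """Write one or more position frames (A) as multi-frame XYZ."""
    frames = [np.asarray(f, dtype=float) for f in np.atleast_3d(frames)]
    if comments is None:
        comments = [""] * len(frames)
    with open(path, "w") as fh:
        for frame, comment in zip(frames, comments):
            fh.write(f"{len(symbols)}\n{comment}\n")
            for sym, (x, y, z) in zip(symbols, frame):
                fh.write(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def write_snapshot_xyz(path, symbols, snapshot: Snapshot) -> None:
    comment = f"time_fs={snapshot.time_fs:.4f} stage={snapshot.stage}"
    write_xyz(path, symbols, [snapshot.positions], [comment])


def read_xyz(path) -> tuple[list[str], list[np.ndarray], list[str]]:
    """Read a multi-frame XYZ file -> (symbols, frames, comments)."""
    frames: list[np.ndarray] = []
    comments: list[str] = []
    symbols: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = int(lines[pos].split()[0])
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        block = lines[pos + 2 : pos + 2 + natoms]
        if len(block) < natoms:
            raise ValueError(f"truncated XYZ frame at line {pos + 1}")
        syms = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if not symbols:
            symbols = syms
        frames.append(coords)
        comments.append(comment)
        pos += 2 + natoms
    return symbols, frames, comments


def write_restart(path, symbols, snapshot: Snapshot) -> None:
    """Write the documented plain-text restart format (positions+velocities)."""
    with open(path, "w") as fh:
        fh.write(f"{RESTART_MAGIC} 1\n")
        fh.write(f"{snapshot.n_atoms} {snapshot.time_fs:.6f} {snapshot.stage}\n")
        for sym, r, v in zip(symbols, snapshot.positions, snapshot.velocities):
            fh.write(
                f"{sym:<3s} {r[0]:18.12f} {r[1]:18.12f} {r[2]:18.12f}"
                f" {v[0]:18.12f} {v[1]:18.12f} {v[2]:18.12f}\n"
            )


def read_restart(path) -> tuple[list[str], Snapshot]:
    """Read the documented restart format -> (symbols, Snapshot)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(RESTART_MAGIC):
        raise ValueError(f"not a {RESTART_MAGIC} file: {path}")
    header = lines[1].split()
    natoms = int(header[0])
    time_fs = float(header[1])
    stage = header[2] if len(header) > 2 else "initial"
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise ValueError("truncated restart file")
    symbols = [ln.split()[0] for ln in body]
    data = np.array([[float(v) for v in ln.split()[1:7]] for ln in body])
    snap = Snapshot(
        positions=data[:, :3], velocities=data[:, 3:6], time_fs=time_fs, stage=stage
    )
    return symbols, snap


def _read_fortran_floats(lines: list[str], n_values: int, width: int = 12) -> np.ndarray:
    values: list[float] = []
    for line in lines:
        line = line.rstrip("\n")
        for start in range(0, len(line), width):
            chunk = line[start : start + width].strip()
            if chunk:
                values.append(float(chunk))
        if len(values) >= n_values:
            break
    if len(values) < n_values:
        raise ValueError("rst7 file ended before all values were read")
    return np.array(values[:n_values])


def read_rst7(path) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Read an AMBER ASCII restart -> (positions A, velocities A/fs, time_ps, natoms).

    Velocities are converted from AMBER units (A per 1/20.455 ps) at the
    boundary.  Only the coordinate+velocity layout is supported (no box line
    handling beyond ignoring a trailing line).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError("rst7 file too short")
    header = lines[1].split()
    natoms = int(header[0])
    time_ps = float(header[1]) if len(header) > 1 else 0.0
    n_coord_lines = -(-3 * natoms // 6)  # 6 values (2 atoms) per line, ceil
    body = lines[2:]
    coords = _read_fortran_floats(body, 3 * natoms).reshape(natoms, 3)
    vel_lines = body[n_coord_lines:]
    velocities = _read_fortran_floats(vel_lines, 3 * natoms).reshape(natoms, 3)
    velocities = velocities * AMBER_VEL_TO_A_FS
    return coords, velocities, time_ps, natoms


def write_rst7(path, positions: np.ndarray, velocities: np.ndarray, time_ps: float = 0.0,
               title: str = "restart") -> None:
    """Write an AMBER-style ASCII restart (used to round-trip the reader)."""
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float) / AMBER_VEL_TO_A_FS
    natoms = positions.shape[0]
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{natoms:5d}{time_ps:15.7e}\n")
        for block in (positions, velocities):
            flat = block.reshape(-1)
            for start in range(0, flat.size, 6):
                chunk = flat[start : start + 6]
                fh.write("".join(f"{v:12.7f}" for v in chunk) + "\n")
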