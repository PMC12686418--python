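"""Phase-space recording, replay and file I/O.

A phase space is the set of particle states (type, energy, position on the
plane, direction, statistical weight) crossing a fixed z plane in the +z
direction.  Recorded once beneath the collimation system, it can be
replayed as a source for downstream geometries (non-reference applicators)
without re-transporting the machine head.

File format: 64-byte little-endian header (8-byte magic ``IOERTPS\\0``,
uint32 version, uint64 record count, float64 plane_z, zero padding) followed
by fixed 36-byte records: int32 type code then 8 float32 values
(E, x, y, u, v, w, weight, spare).  A CSV debug dialect with the same
columns is also provided.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass

import numpy as np

MAGIC = b"IOERTPS\x00"
VERSION = 1
ELECTRON = 0
PHOTON = 1

RECORD_DTYPE = np.dtype([
    ("ptype", "<i4"), ("energy", "<f4"), ("x", "<f4"), ("y", "<f4"),
    ("u", "<f4"), ("v", "<f4"), ("w", "<f4"), ("weight", "<f4"),
    ("spare", "<f4"),
])
assert RECORD_DTYPE.itemsize == 36

_HEADER = struct.Struct("<8sIQd")  # magic, version, count, plane_z


@dataclass(frozen=True)
class PhaseSpaceRecord:
    """Single crossing record (double precision, for construction/tests)."""

    particle_type: int
    energy: float
    x: float
    y: float
    u: float
    v: float
    w: float
    weight: float = 1.0

    def __post_init__(self):
        if abs(self.u ** 2 + self.v ** 2 + self.w ** 2 - 1.0) > 1e-9:
            raise ValueError("direction cosines must be unit-norm within 1e-9")
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def records_from_states(states: list[PhaseSpaceRecord]) -> np.ndarray:
    out = np.zeros(len(states), dtype=RECORD_DTYPE)
    for i, s in enumerate(states):
        out[i] = (s.particle_type, s.energy, s.x, s.y, s.u, s.v, s.w, s.weight, 0.0)
    return out


def write_phase_space(path, records: np.ndarray, plane_z: float) -> None:
    """Write the binary phase-space file (bit-exact roundtrip guaranteed)."""
    header = _HEADER.pack(MAGIC, VERSION, len(records), float(plane_z))
    header = header.ljust(64, b"\x00")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(records, dtype=RECORD_DTYPE).tobytes())


def read_phase_space(path) -> tuple[np.ndarray, float]:
    """Read the binary phase-space file; returns (records, plane_z)."""
    with open(path, "rb") as fh:
        header = fh.read(64)
        if len(header) < 64:
            raise ValueError("truncated phase-space header")
        magic, version, count, plane_z = _HEADER.unpack(header[:_HEADER.size])
        if magic != MAGIC:
            raise ValueError("not a phase-space file (bad magic)")
        if version != VERSION:
            raise ValueError(f"unsupported phase-space version {version}")
        data = fh.read(count * RECORD_DTYPE.itemsize)
    records = np.frombuffer(data, dtype=RECORD_DTYPE, count=count).copy()
    return records, plane_z


_CSV_COLS = ["ptype", "energy", "x", "y", "u", "v", "w", "weight", "spare"]


def write_phase_space_csv(path, records: np.ndarray, plane_z: float) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# plane_z_mm={plane_z!r}\n")
        fh.write(",".join(_CSV_COLS) + "\n")
        for r in records:
            vals = [repr(int(r["ptype"]))] + [repr(float(r[c])) for c in _CSV_COLS[1:]]
            fh.write(",".join(vals) + "\n")


def read_phase_space_csv(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# plane_z_mm="):
            raise ValueError("missing plane_z header line")
        plane_z = float(first.split("=", 1)[1])
        header = fh.readline().strip().split(",")
        if header != _CSV_COLS:
            raise ValueError("unexpected phase-space CSV columns")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    records = np.zeros(len(rows), dtype=RECORD_DTYPE)
    for i, row in enumerate(rows):
        records[i] = (int(row[0]),) + tuple(float(v) for v in row[1:])
    return records, plane_z


def record_phase_space(source, geometry, n_histories: int, config,
                       plane_z: float | None = None) -> np.ndarray:
    """Transport primaries through the machine head, recording plane crossings.

    ``plane_z`` defaults to the geometry's plane beneath the collimation
    system; it must lie inside the machine, upstream of the phantom.  Only
    electrons exist in this engine, so photon/neutron record counts are
    zero by construction.
    """
    from .beam import sample_primary
    from .transport import CHUNK, transport_stack

    if plane_z is None:
        plane_z = geometry.phase_space_z
    if not (0.0 <= plane_z <= geometry.phantom_z):
        raise ValueError(
            f"plane_z={plane_z} outside the geometry [0, {geometry.phantom_z}] mm")
    rng = np.random.default_rng(config.seed)
    chunks = []
    done = 0
    while done < n_histories:
        n = min(CHUNK, n_histories - done)
        states = sample_primary(source, rng, n)
        _, _, rec = transport_stack(states, geometry, config.energy_cutoff,
                                    rng, record_plane_z=plane_z)
        if rec is not None:
            chunks.append(rec)
        done += n
    if not chunks:
        return np.zeros(0, dtype=RECORD_DTYPE)
    return np.concatenate(chunks)


def replay_phase_space(records: np.ndarray, geometry, phantom, config,
                       plane_z: float | None = None):
    """Replay recorded particles through the downstream geometry.

    Statistically equivalent to the original full run below the plane
    (agreement within combined Monte Carlo uncertainty).
    """
    from .transport import run_simulation

    if len(records) == 0:
        raise ValueError("cannot replay an empty phase space")
    return run_simulation(None, geometry, phantom, config,
                          phase_space=records, phase_space_plane_z=plane_z)
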