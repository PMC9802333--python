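"""Trajectory serialization: extended-XYZ text and an HDF5 container.

The extended-XYZ writer emits one frame per time step with per-atom
columns ``pos/vel/accel/mass/charge`` (2-D systems are zero-padded to
three columns; the true dimension travels in the frame header) and frame
fields for the step size, simulation constants and periodic box.  Values
are printed with 17 significant digits so a round trip is bit-faithful.
"""

from __future__ import annotations

import json
import re
import zlib

import numpy as np

from .systems import SystemSpec, Trajectory

__all__ = [
    "write_extxyz",
    "read_extxyz",
    "write_hdf5",
    "read_hdf5",
    "substream",
]


def substream(root_seed, name):
    """Derive a named child seed (< 2**31) from one root seed.

    All randomness in an experiment flows from a single root through named
    substreams (``simulate``, ``split``, ``init``, ``batch``, ``noise``) so
    that components can be re-seeded independently yet reproducibly.
    """
    tag = zlib.crc32(name.encode())
    ss = np.random.SeedSequence([int(root_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


_FMT = "%.17g"


def _species(traj):
    if traj.spec is not None and traj.spec.law == "lj":
        return "Ar"
    return "X"


def write_extxyz(path, traj):
    """Write a trajectory as extended-XYZ (one frame per step)."""
    spec = traj.spec
    sp = _species(traj)
    with open(path, "w") as fh:
        for t in range(traj.n_steps):
            fh.write(f"{traj.n}\n")
            fields = [
                f"dt={_FMT % traj.dt}",
                f"step={t}",
                f"dim={traj.d}",
                f'provenance="{traj.provenance}"',
            ]
            if spec is not None:
                fields.append(f'law="{spec.law}"')
                fields.append(f"constants='{json.dumps(spec.constants)}'")
            if traj.box_length is not None:
                L = _FMT % traj.box_length
                fields.append(f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}"')
            fields.append(
                "Properties=species:S:1:pos:R:3:vel:R:3:accel:R:3:mass:R:1:charge:R:1"
            )
            fh.write(" ".join(fields) + "\n")
            pos = _pad3(traj.positions[t])
            vel = _pad3(traj.velocities[t])
            acc = _pad3(traj.accelerations[t])
            for i in range(traj.n):
                row = np.concatenate(
                    [pos[i], vel[i], acc[i], [traj.masses[i]], [traj.charges[i]]]
                )
                fh.write(sp + " " + " ".join(_FMT % v for v in row) + "\n")


def _pad3(arr):
    if arr.shape[1] == 3:
        return arr
    out = np.zeros((arr.shape[0], 3))
    out[:, : arr.shape[1]] = arr
    return out


_KV_RE = re.compile(r"""(\w+)=('(?:[^'])*'|"(?:[^"])*"|\S+)""")


def _parse_header(line):
    out = {}
    for key, raw in _KV_RE.findall(line):
        if raw and raw[0] in "'\"":
            raw = raw[1:-1]
        out[key] = raw
    return out


def read_extxyz(path):
    """Read a trajectory written by :func:`write_extxyz`."""
    frames = []
    header = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        header = _parse_header(lines[pos + 1])
        rows = [lines[pos + 2 + i].split() for i in range(n)]
        data = np.array([[float(v) for v in r[1:]] for r in rows])
        frames.append((header, data))
        pos += 2 + n
    if not frames:
        raise ValueError("empty extended-XYZ file")
    header = frames[0][0]
    d = int(header.get("dim", 3))
    dt = float(header["dt"])
    T = len(frames)
    n = frames[0][1].shape[0]
    positions = np.empty((T, n, d))
    velocities = np.empty((T, n, d))
    accelerations = np.empty((T, n, d))
    for t, (_, data) in enumerate(frames):
        positions[t] = data[:, 0:d]
        velocities[t] = data[:, 3 : 3 + d]
        accelerations[t] = data[:, 6 : 6 + d]
    masses = frames[0][1][:, 9]
    charges = frames[0][1][:, 10]
    spec = None
    if "law" in header:
        spec = SystemSpec(
            law=header["law"], d=d, constants=json.loads(header.get("constants", "{}"))
        )
    box = None
    if "Lattice" in header:
        box = float(header["Lattice"].split()[0])
    return Trajectory(
        positions,
        velocities,
        accelerations,
        charges,
        masses,
        dt,
        provenance=header.get("provenance", "integrator"),
        box_length=box,
        spec=spec,
    )


def write_hdf5(path, traj):
    """Binary trajectory container for large runs."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("velocities", data=traj.velocities)
        f.create_dataset("accelerations", data=traj.accelerations)
        f.create_dataset("charges", data=traj.charges)
        f.create_dataset("masses", data=traj.masses)
        f.attrs["dt"] = traj.dt
        f.attrs["provenance"] = traj.provenance
        if traj.box_length is not None:
            f.attrs["box_length"] = traj.box_length
        if traj.spec is not None:
            f.attrs["spec"] = traj.spec.to_json()


def read_hdf5(path):
    import h5py

    with h5py.File(path, "r") as f:
        spec = None
        if "spec" in f.attrs:
            spec = SystemSpec.from_json(f.attrs["spec"])
        box = float(f.attrs["box_length"]) if "box_length" in f.attrs else None
        return Trajectory(
            f["positions"][...],
            f["velocities"][...],
            f["accelerations"][...],
            f["charges"][...],
            f["masses"][...],
            float(f.attrs["dt"]),
            provenance=str(f.attrs["provenance"]),
            box_length=box,
            spec=spec,
        )
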