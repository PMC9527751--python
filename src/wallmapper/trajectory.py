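"""Particle-trajectory container and plain-text I/O.

A :class:`Trajectory` holds frames of labeled particles in a laterally
periodic film: x and y are periodic with the given box, z is the
non-periodic surface normal (z = 0 at the wall plane).  The attached
:class:`Topology` gives molecule membership, per-particle species and
mass, and the particle pairs defining molecular bond vectors (the C-C
analogue used for orientation analysis).

Formats: XYZ-with-time (coordinates in angstroms, frame comment carrying
the time and box) plus a small YAML topology file; LAMMPS-style dump
reading is provided for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Topology", "Trajectory", "write_xyz_trajectory",
           "read_xyz_trajectory", "read_lammps_dump",
           "write_topology", "read_topology"]


@dataclass
class Topology:
    """Per-particle species labels and masses, molecule ids, bond pairs."""

    species: list[str]
    masses: np.ndarray
    molecule_ids: np.ndarray
    bond_pairs: np.ndarray  # (B, 2) int, may be empty

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.bond_pairs = np.asarray(self.bond_pairs, dtype=int).reshape(-1, 2)
        n = len(self.species)
        if len(self.masses) != n or len(self.molecule_ids) != n:
            raise ValueError("species, masses, molecule_ids must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.bond_pairs.size:
            if self.bond_pairs.min() < 0 or self.bond_pairs.max() >= n:
                raise ValueError("bond pair references a missing particle")
            a, b = self.bond_pairs[:, 0], self.bond_pairs[:, 1]
            if np.any(self.molecule_ids[a] != self.molecule_ids[b]):
                raise ValueError("bond pairs must join particles of one molecule")

    @property
    def n_particles(self) -> int:
        return len(self.species)


@dataclass
class Trajectory:
    """Frames of particle positions in a laterally periodic film.

    times : (F,) ps, strictly increasing
    positions : (F, N, 3) nm
    box : (lx, ly) lateral periodic lengths, nm
    topology : Topology for the N particles
    """

    times: np.ndarray
    positions: np.ndarray
    box: tuple[float, float]
    topology: Topology

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (F, N, 3)")
        if len(self.times) != self.positions.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape[1] != self.topology.n_particles:
            raise ValueError("particle count must match topology")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Frame interval in ps (requires uniform sampling)."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame interval")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("frames are not uniformly spaced")
        return float(dts[0])

    def unwrapped_xy(self) -> np.ndarray:
        """Laterally unwrapped (F, N, 2) coordinates.

        Frame-to-frame displacements are minimum-imaged in x and y and
        accumulated; z is never wrapped.
        """
        xy = self.positions[:, :, :2]
        disp = np.diff(xy, axis=0)
        for k, L in enumerate(self.box):
            disp[:, :, k] -= L * np.round(disp[:, :, k] / L)
        out = np.empty_like(xy)
        out[0] = xy[0]
        np.cumsum(disp, axis=0, out=out[1:])
        out[1:] += xy[0]
        return out

    def bond_vectors(self, bond_pairs: np.ndarray | None = None) -> np.ndarray:
        """(F, B, 3) bond vectors, minimum-imaged laterally."""
        pairs = self.topology.bond_pairs if bond_pairs is None else np.asarray(bond_pairs, int).reshape(-1, 2)
        if pairs.size == 0:
            raise ValueError("no bond pairs defined")
        v = self.positions[:, pairs[:, 1]] - self.positions[:, pairs[:, 0]]
        for k, L in enumerate(self.box):
            v[:, :, k] -= L * np.round(v[:, :, k] / L)
        return v

    def bond_midpoints(self, bond_pairs: np.ndarray | None = None) -> np.ndarray:
        """(F, B, 3) midpoints of the bond pairs (lateral minimum image)."""
        pairs = self.topology.bond_pairs if bond_pairs is None else np.asarray(bond_pairs, int).reshape(-1, 2)
        if pairs.size == 0:
            raise ValueError("no bond pairs defined")
        return self.positions[:, pairs[:, 0]] + 0.5 * self.bond_vectors(pairs)


def write_topology(top: Topology, path) -> None:
    doc = {
        "species": list(top.species),
        "masses": [float(m) for m in top.masses],
        "molecule_ids": [int(m) for m in top.molecule_ids],
        "bond_pairs": [[int(a), int(b)] for a, b in top.bond_pairs],
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_topology(path) -> Topology:
    doc = yaml.safe_load(Path(path).read_text())
    return Topology(
        species=[str(s) for s in doc["species"]],
        masses=np.asarray(doc["masses"], float),
        molecule_ids=np.asarray(doc["molecule_ids"], int),
        bond_pairs=np.asarray(doc.get("bond_pairs", []), int).reshape(-1, 2),
    )


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """XYZ frames in angstroms; comment: ``time_ps=<t> box_A=<lx> <ly>``."""
    with Path(path).open("w") as fh:
        for t, frame in zip(traj.times, traj.positions):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                f"time_ps={t:.6f} box_A={traj.box[0]*10:.6f} {traj.box[1]*10:.6f}\n"
            )
            for lbl, p in zip(traj.topology.species, frame):
                fh.write(f"{lbl} {p[0]*10:.6f} {p[1]*10:.6f} {p[2]*10:.6f}\n")


def read_xyz_trajectory(path, topology: Topology) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    times, frames = [], []
    box = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i+1}: expected atom count") from exc
        comment = lines[i + 1].split()
        kv = dict(
            tok.split("=", 1) for tok in comment if "=" in tok
        )
        if "time_ps" not in kv:
            raise ValueError(f"{path}:{i+2}: frame comment lacks time_ps=")
        times.append(float(kv["time_ps"]))
        if "box_A" in kv:
            bx = float(kv["box_A"])
            by = float(comment[comment.index(f"box_A={kv['box_A']}") + 1])
            box = (bx / 10.0, by / 10.0)
        coords = []
        for ln in range(i + 2, i + 2 + n):
            parts = lines[ln].split()
            coords.append([float(v) / 10.0 for v in parts[1:4]])
        frames.append(coords)
        i += 2 + n
    if box is None:
        raise ValueError(f"{path}: no box_A metadata found")
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        box=box,
        topology=topology,
    )


def read_lammps_dump(path, topology: Topology) -> Trajectory:
    """Read a LAMMPS text dump (``id type x y z``, coordinates in angstroms,
    timestep interpreted as ps via the TIMESTEP record)."""
    lines = Path(path).read_text().splitlines()
    times, frames = [], []
    box = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("ITEM: TIMESTEP"):
            times.append(float(lines[i + 1].strip()))
            i += 2
        elif line.startswith("ITEM: NUMBER OF ATOMS"):
            n = int(lines[i + 1].strip())
            i += 2
        elif line.startswith("ITEM: BOX BOUNDS"):
            xlo, xhi = map(float, lines[i + 1].split()[:2])
            ylo, yhi = map(float, lines[i + 2].split()[:2])
            box = ((xhi - xlo) / 10.0, (yhi - ylo) / 10.0)
            i += 4
        elif line.startswith("ITEM: ATOMS"):
            cols = line.split()[2:]
            ix, iy, iz = cols.index("x"), cols.index("y"), cols.index("z")
            iid = cols.index("id")
            rows = []
            for ln in range(i + 1, i + 1 + n):
                parts = lines[ln].split()
                rows.append(
                    (int(parts[iid]), float(parts[ix]), float(parts[iy]), float(parts[iz]))
                )
            rows.sort()
            frames.append([[x / 10.0, y / 10.0, z / 10.0] for _, x, y, z in rows])
            i += 1 + n
        else:
            i += 1
    if box is None:
        raise ValueError(f"{path}: no BOX BOUNDS record found")
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        box=box,
        topology=topology,
    )
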