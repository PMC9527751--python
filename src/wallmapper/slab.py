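"""Laterally periodic atomistic slab models with per-atom LJ parameters.

Slabs are the atomistic reference surfaces that get mapped onto 9-3 wall
potentials: a graphite crystal used directly, and pseudo-crystalline
slabs of extended alkane chains lying parallel to the interface, packed
to the experimental liquid density.

Conventions
-----------
* Coordinates are nm internally; XYZ/PDB files are read and written in
  angstroms (the conventional unit of those formats) and converted at I/O.
* ``surface_z`` is the z of the plane through the centers of the
  outermost atom layer (the maximum atom z).  All probe distances in
  :mod:`wallmapper.wall_param` are measured from this plane; any constant
  offset in this convention is absorbed by the fitted sigma_iw.
* ``primitive_cell``, when set by a builder, records the smallest lateral
  period of the structure so lattice sums can fold the slab down to one
  crystallographic cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .potentials import LJPair

__all__ = [
    "AtomRecord",
    "Slab",
    "build_graphite_slab",
    "build_alkane_slab",
    "read_slab",
    "write_slab",
    "read_lj_table",
    "write_lj_table",
]

# graphite lattice constants (nm): in-plane a, interlayer spacing d
GRAPHITE_A = 0.2461
GRAPHITE_INTERLAYER = 0.3354

# all-trans alkane geometry (nm / degrees)
CC_BOND = 0.1526
CCC_ANGLE = 112.0
CH_BOND = 0.1090

MASS = {"C": 12.011, "H": 1.008}
AMU_PER_NM3_TO_G_PER_CM3 = 1.66053907e-3


@dataclass(frozen=True)
class AtomRecord:
    position: tuple[float, float, float]
    type_label: str
    lj: LJPair


@dataclass
class Slab:
    """Atomistic surface model, periodic in x and y.

    Attributes
    ----------
    positions : (N, 3) float array, nm
    type_labels : list of str, one per atom
    lj_table : mapping type_label -> LJPair
    cell : (lx, ly) lateral periodic lengths, nm
    surface_z : z of the outermost atom plane, nm
    primitive_cell : optional (px, py) smallest lateral period, nm
    """

    positions: np.ndarray
    type_labels: list[str]
    lj_table: dict[str, LJPair]
    cell: tuple[float, float]
    surface_z: float
    primitive_cell: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if len(self.type_labels) != len(self.positions):
            raise ValueError("one type label per atom required")
        missing = set(self.type_labels) - set(self.lj_table)
        if missing:
            raise KeyError(
                f"no LJ parameters for atom type(s): {sorted(missing)}"
            )
        if self.cell[0] <= 0 or self.cell[1] <= 0:
            raise ValueError("cell lengths must be positive")
        if np.any(self.positions[:, 2] > self.surface_z + 1e-6):
            raise ValueError("atoms found above surface_z")
        if self.thickness < 3.0 - 1e-9:
            warnings.warn(
                f"slab thickness {self.thickness:.2f} nm is below the "
                "recommended 3 nm minimum",
                stacklevel=2,
            )

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def thickness(self) -> float:
        z = self.positions[:, 2]
        return float(z.max() - z.min())

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(tuple(p), t, self.lj_table[t])
            for p, t in zip(self.positions, self.type_labels)
        ]

    def wrap_lateral(self, positions: np.ndarray) -> np.ndarray:
        """Minimum-image wrap of x, y into [0, lx) x [0, ly)."""
        out = np.array(positions, dtype=float)
        out[..., 0] %= self.cell[0]
        out[..., 1] %= self.cell[1]
        return out


def build_graphite_slab(
    min_dims: tuple[float, float, float],
    carbon_lj: LJPair,
    a: float = GRAPHITE_A,
    interlayer: float = GRAPHITE_INTERLAYER,
    type_label: str = "C",
) -> Slab:
    """AB-stacked hexagonal graphite slab, top basal plane at z = 0.

    The orthorhombic representation of graphene (cell a x sqrt(3) a, four
    atoms per layer) is replicated to cover ``min_dims``; layers are
    stacked downward at the interlayer spacing with the B layers shifted
    by one bond length.  Defaults are the standard lattice constants
    a = 0.2461 nm, d = 0.3354 nm.
    """
    if any(d < 1.0 for d in min_dims):
        raise ValueError("min_dims must each be >= 1 nm")
    px, py = a, math.sqrt(3.0) * a
    nx = math.ceil(min_dims[0] / px)
    ny = math.ceil(min_dims[1] / py)
    nlayers = math.ceil(min_dims[2] / interlayer) + 1

    # fractional in-plane honeycomb positions in the orthorhombic cell
    frac_a = np.array([[0, 0], [0, 1 / 3], [0.5, 0.5], [0.5, 5 / 6]])
    frac_b = (frac_a + [0.0, 1 / 3]) % 1.0

    cells = np.array(
        [(i, j) for i in range(nx) for j in range(ny)], dtype=float
    )
    pos = []
    for layer in range(nlayers):
        frac = frac_a if layer % 2 == 0 else frac_b
        xy = (cells[:, None, :] + frac[None, :, :]).reshape(-1, 2) * [px, py]
        z = np.full((len(xy), 1), -layer * interlayer)
        pos.append(np.hstack([xy, z]))
    positions = np.vstack(pos)

    return Slab(
        positions=positions,
        type_labels=[type_label] * len(positions),
        lj_table={type_label: carbon_lj},
        cell=(nx * px, ny * py),
        surface_z=0.0,
        primitive_cell=(px, py),
    )


def _alkane_chain(n_carbons: int) -> tuple[np.ndarray, list[str]]:
    """All-trans alkane chain extended along x, backbone in the xy plane.

    Returns positions (nm, chain starts at origin) and element labels.
    """
    half = math.radians(CCC_ANGLE / 2.0)
    dx = CC_BOND * math.sin(half)
    dy = CC_BOND * math.cos(half)
    carbons = np.array(
        [[i * dx, (i % 2) * dy, 0.0] for i in range(n_carbons)]
    )
    pos = [carbons]
    labels = ["C"] * n_carbons
    # two out-of-plane hydrogens per carbon; HCH bisector points away
    # from the backbone in -/+y, H's splay in +/-z
    alpha = math.radians(107.0 / 2.0)
    for i, c in enumerate(carbons):
        sign = -1.0 if i % 2 == 0 else 1.0
        for sz in (+1.0, -1.0):
            h = c + [
                0.0,
                sign * CH_BOND * math.cos(alpha),
                sz * CH_BOND * math.sin(alpha),
            ]
            pos.append(h[None, :])
            labels.append("H")
    # terminal hydrogens along the chain axis
    for i, sx in ((0, -1.0), (n_carbons - 1, +1.0)):
        h = carbons[i] + [sx * CH_BOND, 0.0, 0.0]
        pos.append(h[None, :])
        labels.append("H")
    return np.vstack(pos), labels


def build_alkane_slab(
    chain_length: int,
    target_density: float,
    min_dims: tuple[float, float, float],
    lj_table: dict[str, LJPair],
    inter_chain_gap: float = 0.4,
) -> Slab:
    """Pseudo-crystalline slab of extended alkane chains parallel to xy.

    Chains run along x (end-to-end with a van-der-Waals gap of
    ``inter_chain_gap`` nm between periodic images) and are packed on a
    square (y, z) grid whose spacing is solved so the slab mass density
    equals ``target_density`` (g/cm^3) exactly; alternate z layers are
    staggered by half a spacing in y.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    for lbl in ("C", "H"):
        if lbl not in lj_table:
            raise KeyError(f"no LJ parameters for atom type(s): ['{lbl}']")

    chain, labels = _alkane_chain(chain_length)
    half = math.radians(CCC_ANGLE / 2.0)
    pitch = (chain_length - 1) * CC_BOND * math.sin(half) + inter_chain_gap
    mass = chain_length * MASS["C"] + (2 * chain_length + 2) * MASS["H"]
    # per-chain volume pitch * s^2 fixes the grid spacing s
    s = math.sqrt(mass * AMU_PER_NM3_TO_G_PER_CM3 / (target_density * pitch))
    if s < 0.25:
        raise ValueError(
            f"target density {target_density} g/cm^3 requires chain spacing "
            f"{s:.3f} nm < 0.25 nm: geometrically infeasible"
        )

    nx = math.ceil(min_dims[0] / pitch)
    ny = math.ceil(min_dims[1] / s)
    nz = math.ceil(min_dims[2] / s) + 1

    pos = []
    all_labels: list[str] = []
    for k in range(nz):
        y0 = (s / 2.0) * (k % 2)
        for j in range(ny):
            for i in range(nx):
                offset = np.array([i * pitch, y0 + j * s, -k * s])
                pos.append(chain + offset)
                all_labels.extend(labels)
    positions = np.vstack(pos)
    surface_z = float(positions[:, 2].max())

    return Slab(
        positions=positions,
        type_labels=all_labels,
        lj_table=dict(lj_table),
        cell=(nx * pitch, ny * s),
        surface_z=surface_z,
        primitive_cell=(pitch, s),
    )


# ---------------------------------------------------------------------------
# I/O


def read_lj_table(path) -> dict[str, LJPair]:
    """Read a TSV of ``type_label  epsilon_kcal_mol  sigma_nm``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"type_label", "epsilon_kcal_mol", "sigma_nm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"LJ table {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return {
        str(row.type_label): LJPair(float(row.epsilon_kcal_mol), float(row.sigma_nm))
        for row in df.itertuples()
    }


def write_lj_table(table: dict[str, LJPair], path) -> None:
    pd.DataFrame(
        {
            "type_label": list(table),
            "epsilon_kcal_mol": [p.epsilon for p in table.values()],
            "sigma_nm": [p.sigma for p in table.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def write_slab(slab: Slab, path) -> None:
    """Write slab coordinates as XYZ (angstroms) with cell metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{slab.n_atoms}\n")
        fh.write(
            f"cell_A {slab.cell[0] * 10:.6f} {slab.cell[1] * 10:.6f} "
            f"surface_z_A {slab.surface_z * 10:.6f}\n"
        )
        for p, t in zip(slab.positions, slab.type_labels):
            fh.write(
                f"{t} {p[0] * 10:.6f} {p[1] * 10:.6f} {p[2] * 10:.6f}\n"
            )


def _read_xyz(path) -> tuple[np.ndarray, list[str], dict]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}:1: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:1: expected atom count") from exc
    meta: dict = {}
    if len(lines) > 1:
        tokens = lines[1].split()
        for key in ("cell_A", "surface_z_A"):
            if key in tokens:
                i = tokens.index(key)
                nvals = 2 if key == "cell_A" else 1
                meta[key] = [float(v) for v in tokens[i + 1 : i + 1 + nvals]]
    labels, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 'label x y z'")
        labels.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric coordinate") from exc
    if len(coords) != n:
        raise ValueError(f"{path}: header declares {n} atoms, found {len(coords)}")
    return np.asarray(coords), labels, meta


def read_slab(
    coords_file,
    lj_table_file,
    cell: tuple[float, float] | None = None,
) -> Slab:
    """Read a slab from XYZ / PDB / LAMMPS-data coordinates plus a TSV
    LJ parameter table.

    File coordinates are interpreted as angstroms and converted to nm.
    ``surface_z`` is set to the maximum atom z.  The lateral cell is taken
    from file metadata when present (XYZ comment written by
    :func:`write_slab`, PDB CRYST1, LAMMPS box), else from ``cell`` (nm).
    """
    lj_table = read_lj_table(lj_table_file)
    suffix = Path(coords_file).suffix.lower()
    if suffix == ".xyz":
        coords_A, labels, meta = _read_xyz(coords_file)
        if "cell_A" in meta:
            cell = (meta["cell_A"][0] / 10.0, meta["cell_A"][1] / 10.0)
    else:
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(coords_file))
            coords_A = u.atoms.positions.astype(float)
            labels = [str(n) for n in u.atoms.names]
            if u.dimensions is not None and u.dimensions[0] > 0:
                cell = (u.dimensions[0] / 10.0, u.dimensions[1] / 10.0)
    if cell is None:
        raise ValueError(
            f"{coords_file} carries no lateral cell metadata; pass cell=(lx, ly)"
        )
    missing = sorted(set(labels) - set(lj_table))
    if missing:
        raise KeyError(f"no LJ parameters for atom type(s): {missing}")
    positions = np.asarray(coords_A, dtype=float) / 10.0
    return Slab(
        positions=positions,
        type_labels=list(labels),
        lj_table=lj_table,
        cell=cell,
        surface_z=float(positions[:, 2].max()),
    )
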