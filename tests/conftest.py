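import warnings

import numpy as np
import pytest

from wallmapper.data import GRAPHITE_CARBON
from wallmapper.potentials import LJPair
from wallmapper.slab import Slab, build_graphite_slab
from wallmapper.trajectory import Topology, Trajectory


@pytest.fixture(scope="session")
def graphite_slab():
    """Full-size (>= 3 nm) graphite slab used by the parameterization tests."""
    return build_graphite_slab((3.0, 3.0, 3.0), GRAPHITE_CARBON)


@pytest.fixture()
def one_atom_slab():
    """Single atom at the origin in a huge lateral cell (sum = one pair)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Slab(
            positions=np.array([[0.0, 0.0, 0.0]]),
            type_labels=["X"],
            lj_table={"X": LJPair(0.2, 0.3)},
            cell=(200.0, 200.0),
            surface_z=0.0,
        )


def make_trajectory(positions, dt=1.0, box=(10.0, 10.0), bonds=(), mol_ids=None,
                    species=None, masses=None):
    """Helper to build small hand-crafted trajectories.

    positions: (F, N, 3) array-like, nm.
    """
    positions = np.asarray(positions, float)
    n = positions.shape[1]
    top = Topology(
        species=list(species) if species is not None else ["S"] * n,
        masses=np.asarray(masses, float) if masses is not None else np.full(n, 75.07),
        molecule_ids=np.asarray(mol_ids, int) if mol_ids is not None else np.arange(n),
        bond_pairs=np.asarray(bonds, int).reshape(-1, 2),
    )
    return Trajectory(
        times=dt * np.arange(positions.shape[0]),
        positions=positions,
        box=box,
        topology=top,
    )


@pytest.fixture()
def make_traj():
    return make_trajectory
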