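import numpy as np
import pytest

from arrestkin.core import AnalysisConfig, Entity, Topology, Trajectory
from arrestkin.synth import default_tunnel, default_variant_configs


@pytest.fixture(scope="session")
def configs():
    return default_variant_configs()


@pytest.fixture(scope="session")
def tunnel():
    return default_tunnel()


@pytest.fixture()
def analysis():
    return AnalysisConfig()


def make_topology(ap_positions, other_positions=(), other_entity=Entity.RIBOSOME,
                  ap_start=237):
    """Single-bead-per-residue topology: AP beads then partner atoms."""
    n_ap = len(ap_positions)
    n_other = len(other_positions)
    return Topology(
        atom_id=np.arange(1, n_ap + n_other + 1),
        atom_name=np.array(["CA"] * n_ap + ["P"] * n_other, dtype=object),
        residue_seq=np.array(
            list(range(ap_start, ap_start + n_ap))
            + list(range(1000, 1000 + n_other)), dtype=int),
        residue_name=np.array(["UNK"] * (n_ap + n_other), dtype=object),
        entity=np.array([Entity.AP.value] * n_ap
                        + [other_entity.value] * n_other, dtype=object),
        is_heavy=np.ones(n_ap + n_other, dtype=bool),
        is_calpha=np.array([True] * n_ap + [False] * n_other),
    )


def make_trajectory(frames, topology, dt=1.0, variant="test"):
    """Trajectory from a list of (n_atoms, 3) frames at uniform spacing."""
    coords = np.asarray(frames, dtype=float)
    times = np.arange(coords.shape[0]) * dt
    traj = Trajectory(topology, times, coords, variant=variant)
    traj.validate()
    return traj
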