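import numpy as np
import pytest

from endstate_lie.calculators import CalculatorSpec, mock_pair_potential
from endstate_lie.fixtures import ToySystemSpec, make_toy_trajectory


@pytest.fixture(scope="session")
def toy_system():
    """A solvated toy complex with ions: 5 jittered frames + index groups."""
    spec = ToySystemSpec(
        n_receptor_atoms=10, n_ligand_atoms=4, n_waters=15, n_ions=2, seed=11
    )
    return make_toy_trajectory(spec, n_frames=5, jitter=0.05)


@pytest.fixture(scope="session")
def toy_frame(toy_system):
    traj, _ = toy_system
    return traj.frames[0]


@pytest.fixture(scope="session")
def toy_selection(toy_system):
    _, selection = toy_system
    return selection


@pytest.fixture
def mock_spec():
    return CalculatorSpec(backend="MOCK_PAIRWISE")


def brute_force_mock_energy(elements, coords, table=None):
    """O(N^2) double-loop total energy; the oracle for the mock backend."""
    coords = np.asarray(coords, dtype=float)
    total = 0.0
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            total += mock_pair_potential(elements[i], elements[j], r, table=table)
    return total


def brute_force_cross_energy(els_a, xyz_a, els_b, xyz_b, table=None):
    """O(N_a * N_b) cross-pair sum; the oracle for group-group interactions."""
    xyz_a = np.asarray(xyz_a, dtype=float)
    xyz_b = np.asarray(xyz_b, dtype=float)
    total = 0.0
    for i, el_i in enumerate(els_a):
        for j, el_j in enumerate(els_b):
            r = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            total += mock_pair_potential(el_i, el_j, r, table=table)
    return total
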