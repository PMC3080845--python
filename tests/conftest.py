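import numpy as np
import pytest

from popshift.ensemble import ConformerEnsemble, Topology
from popshift.synthetic import BasinSpec, ToySystem, make_toy_system, sample_metropolis


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def bead_ensemble(frames: np.ndarray) -> ConformerEnsemble:
    """Wrap raw (n_frames, n_atoms, 3) coordinates as a Calpha bead ensemble."""
    n = frames.shape[1]
    return ConformerEnsemble(
        atom_id=np.arange(1, n + 1),
        res_id=np.arange(1, n + 1),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        frames=frames,
    )


@pytest.fixture
def random_ensemble(rng):
    """Small random 6-frame, 8-bead ensemble used by brute-force oracles."""
    base = rng.normal(0.0, 4.0, size=(8, 3))
    frames = base[None] + rng.normal(0.0, 0.7, size=(6, 8, 3))
    return bead_ensemble(frames)


@pytest.fixture
def uniform_topology():
    def make(n, charge=0.1):
        return Topology(
            charge=np.full(n, charge),
            lj_sigma=np.full(n, 3.4),
            lj_epsilon=np.full(n, 0.1),
            born_radius=np.full(n, 1.7),
        )

    return make


@pytest.fixture(scope="session")
def two_basin_1d():
    """1D two-basin toy system (stiff in y/z) with analytically known
    substate populations."""
    basins = [
        BasinSpec([-2.0, 0.0, 0.0], [0.5, 5.0, 5.0], 0.0, "A"),
        BasinSpec([2.0, 0.0, 0.0], [0.5, 5.0, 5.0], 0.1, "B"),
    ]
    return ToySystem(basins, 300.0, np.zeros((1, 3)))


@pytest.fixture(scope="session")
def two_basin_samples(two_basin_1d):
    return sample_metropolis(two_basin_1d, 100_000, step_size=0.9, seed=11)


@pytest.fixture(scope="session")
def default_free_ensemble():
    """The default synthetic free-state ensemble (three-substate preset)."""
    system = make_toy_system(5, temperature=300.0, seed=0)
    return system, sample_metropolis(system, 200_000, step_size=0.25, seed=1)
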