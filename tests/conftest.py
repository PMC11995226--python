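import numpy as np
import pytest

from chamscope.core import Conformer, Ensemble, MoleculeTopology


@pytest.fixture
def toy_topology() -> MoleculeTopology:
    """5-atom chain C-C-O-C-H with the hydrogen on the terminal carbon."""
    return MoleculeTopology(
        elements=["C", "C", "O", "C", "H"],
        bonds=[(0, 1), (1, 2), (2, 3), (3, 4)],
        proton_labels={4: "H1"},
    )


@pytest.fixture
def toy_ensemble(toy_topology) -> Ensemble:
    rng = np.random.default_rng(42)
    base = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.3, 1.2, 0.0],
            [3.8, 1.2, 0.3],
            [4.4, 2.1, 0.3],
        ]
    )
    conformers = [
        Conformer(base + 0.3 * rng.normal(size=base.shape), energy=float(k), conformer_id=str(k))
        for k in range(3)
    ]
    return Ensemble(topology=toy_topology, conformers=conformers)


@pytest.fixture
def random_cluster():
    """Factory for random compact atom clusters used in SASA/R_gyr tests."""

    def make(n_atoms: int, seed: int, spread: float = 2.0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=spread, size=(n_atoms, 3))
        radii = rng.uniform(1.2, 2.0, size=n_atoms)
        return coords, radii

    return make
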