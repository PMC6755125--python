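import numpy as np
import pytest

from saxsemble.poolgen import PoolConfig, sample_pool
from saxsemble.structmodel import Conformer
from saxsemble.synthetic import make_toy_complex, make_two_state_truth


def bead_conformer(coords, model_id="fixture", residue_names=None,
                   chain="A") -> Conformer:
    """Cα-bead conformer from a bare coordinate array."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return Conformer(
        model_id=model_id,
        chain_ids=np.array([chain] * n, dtype=object),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(residue_names or ["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        coords=coords,
        is_coarse=True,
    )


def uniform_sphere_cloud(n, radius, seed=0, model_id="sphere") -> Conformer:
    """n beads drawn uniformly from a solid sphere (no packing constraint)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return bead_conformer(u * r[:, None], model_id=model_id)


@pytest.fixture(scope="session")
def toy():
    """Small two-domain toy complex shared across tests."""
    topology, sources = make_toy_complex(seed=101)
    return topology, sources


@pytest.fixture(scope="session")
def toy_pool(toy):
    topology, _ = toy
    return sample_pool(topology, PoolConfig(n_models=30, seed=202))


@pytest.fixture(scope="session")
def two_state_truth():
    return make_two_state_truth(seed=303)
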