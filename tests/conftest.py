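import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from allopep.trajectory_io import Trajectory


def make_trajectory(coords, chains=None, resids=None, names=None, interval=100.0):
    """Small labelled trajectory from a (frames, atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "chain": chains if chains is not None else ["A"] * n,
            "resid": resids if resids is not None else list(range(1, n + 1)),
            "resname": "GLY",
            "name": names if names is not None else ["CA"] * n,
        }
    )
    return Trajectory(coords=coords, atoms=atoms, frame_interval_ps=interval)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_decoys(rng):
    """Unstructured random decoy table: 4 receptors x 8 peptides x 3 clusters."""
    receptors = [f"R{i}" for i in range(4)]
    peptides = [f"{x}AAL{z}" for x, z in zip("ACDEFGHK", "KHGFEDCA")]
    rows = []
    for r in receptors:
        for p in peptides:
            energies = np.sort(rng.normal(-9.0, 2.0, 3))
            for k, e in enumerate(energies, start=1):
                rows.append((r, p, k, e))
    return pd.DataFrame(rows, columns=["receptor_id", "peptide", "cluster_rank", "energy_kcal_mol"])
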