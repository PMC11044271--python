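import numpy as np
import pytest

from swishx.engine import (
    PairTable,
    ParticleSystem,
    GatedCavitySpec,
    build_gated_cavity_system,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ws_pair():
    """One solvent + one apolar solute particle near the LJ minimum."""
    return ParticleSystem(
        positions=np.array([[0.0, 0.0, 0.0], [2.0 ** (1 / 6), 0.0, 0.0]]),
        roles=["solvent", "solute_apolar"],
        pair_params=PairTable.uniform(),
    )


@pytest.fixture
def random_mixed_system(rng):
    """10 particles of mixed roles, placed without overlaps."""
    pos = []
    while len(pos) < 10:
        cand = rng.uniform(-3, 3, 3)
        if all(np.linalg.norm(cand - p) > 0.9 for p in pos):
            pos.append(cand)
    roles = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3, 0])
    return ParticleSystem(
        positions=np.array(pos), roles=roles, pair_params=PairTable.uniform()
    )


@pytest.fixture(scope="session")
def gated_system():
    spec = GatedCavitySpec(seed=7, n_probe=2)
    return build_gated_cavity_system(spec), spec
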