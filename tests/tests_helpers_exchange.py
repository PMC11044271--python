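"""Shared helper: a frozen two-configuration toy for exchange statistics."""

import numpy as np

from swishx.engine import PairTable, ParticleSystem
from swishx.orchestrator import Replica, _SystemContext

_SYSTEM = ParticleSystem(
    positions=np.array([[0.0, 0.0, 0.0], [1.15, 0.0, 0.0]]),
    roles=["solvent", "solute_apolar"],
    pair_params=PairTable.uniform(),
)
_CTX = _SystemContext(_SYSTEM, None)
_POS_B = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])


def frozen_pair(lam_i=2.0, lam_j=1.0, same_positions=False, T=1.0):
    """Two replicas holding fixed configurations of a single ws pair."""
    mk = lambda lam, pos, wid: Replica(
        lam=lam,
        positions=pos.copy(),
        velocities=np.zeros((2, 3)),
        temperature=T,
        walker_id=wid,
        context=_CTX,
    )
    pos_j = _SYSTEM.positions if same_positions else _POS_B
    return mk(lam_i, _SYSTEM.positions, 0), mk(lam_j, pos_j, 1)
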