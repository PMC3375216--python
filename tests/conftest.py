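import numpy as np
import pytest

import plaquedyn as pq


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba compilation once so individual tests time cleanly."""
    p = pq.LatticeParams(R=0.1, D=0.0, B=0.1, A=0.1, N=5, max_steps=2,
                         seed=0)
    pq.run(p, pq.InitCondition(scheme=pq.CENTER_SQUARE_IN_FULL,
                               infected_side=1), record_every=1)
    mp = pq.MetapopParams(r=0.1, beta=0.1, a=0.1, k=10, n=3, t_max=0.5,
                          seed=0)
    pq.simulate(mp, pq.init_metapop(mp, flank_patches=1),
                snapshot_times=np.array([0.5]))


@pytest.fixture
def nested_init():
    return pq.InitCondition(scheme=pq.NESTED_SQUARES, infected_side=5,
                            susceptible_side=13)


@pytest.fixture
def full_init():
    return pq.InitCondition(scheme=pq.CENTER_SQUARE_IN_FULL,
                            infected_side=30)
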