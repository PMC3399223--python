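import numpy as np
import pytest

import chemocline as cc


@pytest.fixture(scope="session")
def three_group_sim():
    """Noisy three-group community (duplicate-run noise model)."""
    spec = cc.three_group_spec(seed=11)
    return cc.simulate_community(spec, cc.NoiseModel())


@pytest.fixture(scope="session")
def three_group_clean():
    """Noise-free three-group community (exact group structure)."""
    spec = cc.three_group_spec(seed=7)
    return cc.simulate_community(spec, noise=None)


def random_resemblance(rng: np.random.Generator, n: int) -> cc.ResemblanceMatrix:
    """Random symmetric similarity matrix in (0, 100), diagonal 100."""
    sim = rng.uniform(5.0, 95.0, size=(n, n))
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 100.0)
    ids = tuple(f"s{i}" for i in range(n))
    return cc.ResemblanceMatrix(ids, sim)
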