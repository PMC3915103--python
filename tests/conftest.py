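import numpy as np
import pytest

import atlasfuse as af


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return af.VolumeImage(rng.uniform(0, 100, size=(8, 8, 8)))


def random_blob(shape, seed, n_seeds=3):
    """Connected-ish random binary mask: union of random balls."""
    rng = np.random.default_rng(seed)
    grid = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    mask = np.zeros(shape, bool)
    for _ in range(n_seeds):
        c = rng.uniform(2, np.array(shape) - 3)
        r = rng.uniform(1.5, min(shape) / 3)
        mask |= sum((grid[a] - c[a]) ** 2 for a in range(3)) <= r**2
    return mask


@pytest.fixture(scope="session")
def default_population():
    """One three-mode phantom population with oracle registrations, shared
    across tests that only read from it."""
    pop = af.make_population(af.PopulationSpec(seed=7, base=af.PhantomSpec(seed=7)))
    regs = af.oracle_registrations(pop)
    return pop, regs
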