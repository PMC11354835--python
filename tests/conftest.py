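import numpy as np
import pytest

import wingmorph as wm


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete study-shaped simulation: 4 reference panels,
    6 apiaries of 2 colonies x 5 wings, placebo outgroup."""
    cfg = wm.SimulationConfig(
        seed=7, n_apiaries=6, colonies_per_apiary=2, wings_per_colony=5,
        n_per_reference=12,
    )
    return wm.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_gpa(small_sim):
    return wm.GeneralizedProcrustes(small_sim.dataset).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_shape(rng, k):
    """A non-degenerate random landmark configuration."""
    while True:
        coords = rng.normal(size=(k, 2))
        if np.linalg.matrix_rank(coords - coords.mean(axis=0)) == 2:
            return coords


def similarity_transform(coords, rng, reflect=False):
    """Random rotation + translation + positive scaling of a configuration."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    r = np.array([[c, s], [-s, c]])
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-10, 10, size=2)
    return coords @ r * scale + shift
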