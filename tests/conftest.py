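import numpy as np
import pytest

from betaturn.synthetic import FixtureSpec, make_feature_world


@pytest.fixture(scope="session")
def tiny_world():
    """A small planted feature world for fast model-level tests (~180 samples)."""
    spec = FixtureSpec(n_chains=4, chain_length_range=(44, 60), seed=11)
    samples, labels, cluster_ids = make_feature_world(spec)
    return samples, labels, cluster_ids


@pytest.fixture(scope="session")
def desk_world():
    """The full desk-scale planted fixture (~2000 samples, 1:3 class ratio)."""
    spec = FixtureSpec(seed=7)
    samples, labels, cluster_ids = make_feature_world(spec)
    return samples, labels, cluster_ids


def random_trace_coords(rng: np.random.Generator, length: int) -> np.ndarray:
    """A compact random walk producing a mix of sub- and super-cutoff d(i, i+3)."""
    steps = rng.normal(scale=2.2, size=(length - 1, 3))
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
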