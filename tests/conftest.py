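import numpy as np
import pytest

from vansip import pipeline
from vansip.simulate import SimulationConfig, default_community, simulate_dataset


@pytest.fixture(scope="session")
def demo_dataset():
    """One seed-fixed run of the default synthetic scenario:
    100 OTUs (10 labeled at atom fraction 0.9), full 2x3x3 design."""
    taxa = default_community()
    cfg = SimulationConfig(seed=1)
    samples, table, truth = simulate_dataset(taxa, cfg)
    return samples, table, truth


@pytest.fixture(scope="session")
def demo_peaks(demo_dataset):
    samples, _, _ = demo_dataset
    return pipeline.assign_peaks(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
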