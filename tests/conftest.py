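import numpy as np
import pytest

from txrefine.pipeline import inputs_from_dataset, run_pipeline
from txrefine.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions under one fixed seed."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default dataset."""
    return run_pipeline(inputs_from_dataset(default_dataset))


@pytest.fixture()
def rng():
    return np.random.default_rng(20150624)


def random_sequence(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
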