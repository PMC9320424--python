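import logging

import numpy as np
import pytest

from regvar.background import estimate_markov
from regvar.pipeline import PipelineParams, run_pipeline
from regvar.simulate import SimulationConfig, simulate

logging.getLogger("regvar").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated dataset, shared across tests."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def run_default(sim_default):
    """Full pipeline run on the shared dataset."""
    return run_pipeline(sim_default, PipelineParams(seed=1))


@pytest.fixture(scope="session")
def uniform_bg():
    """Order-0 uniform background."""
    return estimate_markov(["ACGT" * 30], order=0, pseudocount=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
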