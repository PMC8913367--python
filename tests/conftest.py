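import numpy as np
import pandas as pd
import pytest

from ecolegacy.diversity import diversity_table
from ecolegacy.inference import SamplerConfig, fit
from ecolegacy.params import ModelSpec
from ecolegacy.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Noise-free synthetic dataset (90 segments) with exact ENS targets."""
    cfg = SimulationConfig(n_routes=30, rng_seed=11, poisson_replication=False)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_dataset):
    div = diversity_table(small_dataset.abundance, {"t1": 2001, "t2": 2016})
    return small_dataset.inputs(div)


@pytest.fixture(scope="session")
def tiny_fit(small_inputs):
    """A short real NUTS fit shared by posterior-consuming tests."""
    spec = ModelSpec(equilibrium_form="quadratic")
    draws, diags = fit(
        spec,
        small_inputs,
        SamplerConfig(chains=2, iterations=250, warmup=250, seed=3, max_extensions=0),
    )
    return spec, draws, diags


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
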