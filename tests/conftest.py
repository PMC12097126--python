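"""Shared fixtures: one small synthetic dataset reused across modules."""

import numpy as np
import pytest

from apadyn import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_genes=80, seed=20240701)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pau(small_dataset):
    from apadyn import quantify
    return quantify.compute_pau(small_dataset.quant)


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    from apadyn import seqfeat
    return seqfeat.extract_pas_windows(small_dataset.genome,
                                       small_dataset.pas_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
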