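import numpy as np
import pytest

from pankinet import (SyntheticConfig, TrainConfig,
                      gen_classification_benchmark, split_set, train)
from pankinet.io import PipelineConfig, featurize_set


@pytest.fixture(scope="session")
def small_benchmark():
    """200-compound planted-motif benchmark shared across test modules."""
    return gen_classification_benchmark(SyntheticConfig(n_compounds=200, seed=7))


@pytest.fixture(scope="session")
def small_graphs(small_benchmark):
    return featurize_set(small_benchmark.structures, PipelineConfig())


@pytest.fixture(scope="session")
def small_trained(small_benchmark, small_graphs):
    """A trained model on the small benchmark (full 100 epochs)."""
    split = split_set(small_benchmark.pkfi_set, 0.8, seed=7)
    params = train(split, small_graphs, TrainConfig(epochs=100, seed=7))
    return params, split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: SMILES of common drug-like molecules used across tests.
PROBE_SMILES = [
    "c1ccccc1",                      # benzene
    "CC(=O)Oc1ccccc1C(=O)O",         # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",    # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",    # ibuprofen
    "c1ccc2[nH]ccc2c1",              # indole
    "N#Cc1ccncc1",                   # 4-cyanopyridine
    "NS(=O)(=O)c1ccccc1",            # benzenesulfonamide
    "OCC1OC(O)C(O)C(O)C1O",          # glucose
    "CN1CCC[C@H]1c1cccnc1",          # nicotine
    "Clc1ccc(cc1)C(F)(F)F",          # aryl-CF3
]


@pytest.fixture(scope="session")
def probe_smiles():
    return list(PROBE_SMILES)
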