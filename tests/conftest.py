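import numpy as np
import pytest

from seqscreen.benchmark import BenchmarkConfig, train_benchmark_model
from seqscreen.plm import ToyEmbedder


@pytest.fixture(scope="session")
def toy_embedder():
    return ToyEmbedder()


@pytest.fixture(scope="session")
def trained_benchmark():
    """Desk-scale model trained once on the reference planted-rule dataset
    (seed 0); shared by the end-to-end enrichment and reverse-screening
    tests.  This is the expensive fixture (several minutes)."""
    result, dataset, embedder = train_benchmark_model(BenchmarkConfig(seed=0))
    return result, dataset, embedder


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
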