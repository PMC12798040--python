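import numpy as np
import pytest

from dssmreg.evaluation import PipelineConfig
from dssmreg.gene_embeddings import AutoencoderConfig
from dssmreg.synthetic_data import SimulationConfig, fixture_library, simulate_dataset
from dssmreg.types import ExpressionMatrix


@pytest.fixture(scope="session")
def default_bundle():
    """One default simulated bundle shared across the session."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sim_pipeline_config():
    return PipelineConfig.for_simulation()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library()


@pytest.fixture
def fast_ae_config():
    """A small, quickly-trainable autoencoder config for unit tests."""
    return AutoencoderConfig(
        hidden_width=64, embed_dim=8, epochs=5, learning_rate=1e-3, batch_size=32, seed=0
    )


@pytest.fixture
def small_counts():
    """Deterministic 6 genes x 5 cells raw count matrix."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(6, 5)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0  # avoid all-zero rows
    return ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(6)],
        [f"c{j}" for j in range(5)],
        is_normalized=False,
    )
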