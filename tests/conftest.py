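import numpy as np
import pytest

from hanppis.config import TrainConfig
from hanppis.fragmenter import build_dataset
from hanppis.io_features import ProteinRecord
from hanppis.synthetic import SynthConfig, generate_proteins, synth_feature_source


@pytest.fixture
def tiny_config():
    """Small network for fast unit tests (architecture logic is size-free)."""
    return TrainConfig(
        hidden=6, attention=5, projection=4, embed_dim=12, epochs=2, seed=7,
        val_fraction=0.0,
    )


@pytest.fixture
def sample_record():
    return ProteinRecord("p1", "RDAKDYA", np.array([0, 0, 0, 1, 0, 0, 0]))


@pytest.fixture(scope="session")
def tiny_corpus():
    cfg = SynthConfig(n_proteins=12, min_len=20, max_len=40, seed=5)
    records, plants = generate_proteins(cfg)
    source = synth_feature_source(records, sigma=0.0, seed=5, embed_dim=12)
    return records, plants, source


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    records, _, source = tiny_corpus
    cfg = TrainConfig(
        hidden=6, attention=5, projection=4, embed_dim=12, epochs=2, seed=7,
        val_fraction=0.0,
    )
    return build_dataset(records, source, cfg), cfg
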