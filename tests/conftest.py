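import numpy as np
import pytest

from spanccd import EncoderConfig, GenConfig, generate_corpus, make_toy_schema
from spanccd.encoder import build_vocab, init_params


@pytest.fixture(scope="session")
def schema():
    return make_toy_schema()


@pytest.fixture(scope="session")
def small_corpus(schema):
    docs, _ = generate_corpus(GenConfig(n_docs=12, seed=41), schema)
    return docs


@pytest.fixture(scope="session")
def tiny_config():
    return EncoderConfig(
        hidden_dim=16, dropout=0.0, n_encoder_layers=1, n_encoder_heads=2, seed=0
    )


@pytest.fixture(scope="session")
def tiny_params(schema, small_corpus, tiny_config):
    return init_params(tiny_config, schema, build_vocab(small_corpus))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
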