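import numpy as np
import pytest

from mtmolgen import chem, synthdata
from mtmolgen.model import ModelConfig, SmilesVAE


@pytest.fixture(scope="session")
def vocab() -> chem.Vocabulary:
    return chem.Vocabulary.default()


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    return synthdata.make_pretrain_corpus(60, seed=11)


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    """Small variant config for fast attention/decoder tests."""
    return ModelConfig(embed_dim=16, n_heads=2, n_encoder_layers=1,
                       n_decoder_layers=1, latent_dim=8, region_size=5,
                       routing_topk=2, max_len=20, seed=3)


@pytest.fixture()
def tiny_model(tiny_cfg, vocab) -> SmilesVAE:
    return SmilesVAE(tiny_cfg, vocab)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
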