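import numpy as np
import pytest

from fp2mol import codecs, corpus, pairs
from fp2mol.model import ModelConfig, Transformer


@pytest.fixture(scope="session")
def small_corpus():
    cfg = corpus.CorpusConfig(n_molecules=150, seed=7)
    return corpus.generate_molecules(cfg)


@pytest.fixture(scope="session")
def toy_pairs(small_corpus):
    return pairs.build_pairs(small_corpus[:40], "AEs", codecs.SMILES)


@pytest.fixture(scope="session")
def toy_vocabs(toy_pairs):
    return pairs.build_vocabularies(toy_pairs)


@pytest.fixture(scope="session")
def toy_model(toy_vocabs):
    sv, tv = toy_vocabs
    cfg = ModelConfig(
        src_vocab_size=len(sv), tgt_vocab_size=len(tv),
        n_layers=2, n_heads=4, d_model=32, d_ff=64, dropout=0.1,
        max_src_len=128, max_tgt_len=64,
    )
    return Transformer(cfg, seed=0)


@pytest.fixture(scope="session")
def toy_encoded(toy_pairs, toy_vocabs):
    sv, tv = toy_vocabs
    return pairs.encode_pairs(toy_pairs, sv, tv)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
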