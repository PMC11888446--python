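import numpy as np
import pytest

from ablm_curriculum.prep import (SeparatorPolicy, build_vocabulary,
                                  encode_record)
from ablm_curriculum.repertoire import generate_repertoire


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary(SeparatorPolicy.from_name("sep"))


@pytest.fixture(scope="session")
def policy():
    return SeparatorPolicy.from_name("sep")


@pytest.fixture(scope="session")
def small_repertoire():
    """300 paired + 400 unpaired chains, fixed seed."""
    return generate_repertoire(300, 200, 200, mutation_rate=6.0,
                               naive_fraction=0.5, seed=1234)


@pytest.fixture(scope="session")
def tokenized_pools(small_repertoire, vocab, policy):
    pairs, unpaired = small_repertoire
    paired_tok = [encode_record(p, vocab, policy) for p in pairs]
    unpaired_tok = [encode_record(u, vocab, policy) for u in unpaired]
    return paired_tok, unpaired_tok


class StaticOracle:
    """Stateless oracle: emits a huge logit for the id stored at each
    position of a reference ids array, matched to the query batch by a
    rolling cursor (callers iterate the dataset in order)."""

    def __init__(self, true_ids: np.ndarray, vocab_size: int = 33, big: float = 50.0):
        self.true_ids = true_ids
        self.vocab_size = vocab_size
        self.big = big
        self.cursor = 0

    def forward(self, ids, attention_mask):
        B, L = ids.shape
        chunk = self.true_ids[self.cursor:self.cursor + B, :L]
        self.cursor += B
        logits = np.zeros((B, L, self.vocab_size))
        rows, cols = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
        logits[rows, cols, chunk] = self.big
        return logits


class UniformModel:
    """All-zero logits: a uniform distribution over the 33 tokens."""

    def __init__(self, vocab_size: int = 33):
        self.vocab_size = vocab_size

    def forward(self, ids, attention_mask):
        B, L = ids.shape
        return np.zeros((B, L, self.vocab_size))


@pytest.fixture
def uniform_model():
    return UniformModel()
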