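"""Shared fixtures: a memorized toy model (trained once per session) and a
small random model for decoding property tests."""

from __future__ import annotations

import numpy as np
import pytest

from itemforge import (
    ModelConfig,
    TrainSchedule,
    build_prompt,
    fit_vocab,
    gen_item_corpus,
    train,
)
from itemforge.synthetic import corpus_to_examples, memorization_grammar


class MemorizedModel:
    """A miniature transformer trained to memorize a 20-label toy corpus
    under the conditional (prompt-masked) objective."""

    def __init__(self) -> None:
        self.corpus = gen_item_corpus(memorization_grammar(20), 20, seed=1)
        self.examples = corpus_to_examples(self.corpus)
        self.vocab = fit_vocab(self.examples)
        self.sequences = [self.vocab.encode_ids(ex.encoded) for ex in self.examples]
        prompt_lengths = [
            len(self.vocab.encode_ids(build_prompt(list(ex.labels))))
            for ex in self.examples
        ]
        n_ctx = max(len(s) for s in self.sequences)
        self.config = ModelConfig(
            vocab_size=self.vocab.size, d_model=48, n_heads=2, n_layers=2,
            n_ctx=n_ctx, d_ff=96, seed=0,
        )
        self.params, self.loss_trace = train(
            self.sequences, self.config,
            TrainSchedule(steps=2000, lr=5e-4),
            prompt_lengths=prompt_lengths,
        )


@pytest.fixture(scope="session")
def memorized():
    return MemorizedModel()


@pytest.fixture()
def random_model():
    """Untrained model with a non-degenerate random output distribution."""
    cfg = ModelConfig(vocab_size=8, d_model=8, n_heads=2, n_layers=1,
                      n_ctx=10, d_ff=16, seed=11, init_std=0.5)
    from itemforge import init_params

    return init_params(cfg), cfg


def make_random_model(seed: int, vocab_size: int = 8):
    from itemforge import init_params

    cfg = ModelConfig(vocab_size=vocab_size, d_model=8, n_heads=2, n_layers=1,
                      n_ctx=12, d_ff=16, seed=seed, init_std=0.5)
    return init_params(cfg), cfg
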