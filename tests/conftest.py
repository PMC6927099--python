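"""Shared fixtures: a small trained model reused by tagger-level and
error-analysis tests (training once per session keeps the suite fast)."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from clinner.embedding_spaces import InputDescriptor, train_space
from clinner.neural_tagger import TaggerConfig, predict, train
from clinner.synthetic_data import (
    generate_dataset,
    generate_raw_corpus,
    profile_config,
)


@pytest.fixture(scope="session")
def small_run():
    """A complete small-scale pipeline run on profile A.

    Default generator rates (misspellings, abbreviations, ambiguity,
    30% unseen test mentions), in-domain embeddings, and a reduced
    network so training stays around ten seconds.
    """
    cfg = profile_config("A", seed=11)
    res = generate_dataset(cfg)
    raw = generate_raw_corpus(cfg, overlap=1.0)
    space = train_space(raw, "word2vec", dimension=50, window=5, epochs=3, seed=11)
    descriptor = InputDescriptor("W", word_space=space)
    tagger_cfg = TaggerConfig(
        lstm_hidden_units=100,
        char_hidden_units=50,
        char_embedding_dim=50,
        max_epochs=15,
        seed=11,
    )
    model, report = train(tagger_cfg, res.split, descriptor)
    test_pred = predict(model, res.split.test)
    return SimpleNamespace(
        config=cfg,
        result=res,
        split=res.split,
        space=space,
        descriptor=descriptor,
        model=model,
        report=report,
        test_pred=test_pred,
    )
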