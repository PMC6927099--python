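"""Tagger components: character encoder, training loop, decoding."""

import numpy as np
import pytest

import clinner.neural_tagger as nt
from clinner.corpus_io import (
    AnnotatedCorpus,
    AnnotatedSentence,
    DataSplit,
    EntityMention,
    Token,
    label_set,
    spans_to_bio,
)
from clinner.embedding_spaces import (
    EmbeddingSpace,
    InputDescriptor,
    cosine_similarity,
)
from clinner.evaluation import EXACT, score
from clinner.neural_tagger import (
    TaggerConfig,
    TaggerModel,
    batch_loss_and_grads,
    build_char_vocab,
    build_token_input,
    encode_characters,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)


def _tiny_setup(seed=0):
    sents = [
        AnnotatedSentence(
            [Token("ab", "ab"), Token("cde", "cde"), Token("f", "f")],
            frozenset([EntityMention("X", 1, 3)]),
        ),
        AnnotatedSentence(
            [Token("cde", "cde"), Token("gg", "gg")],
            frozenset([EntityMention("Y", 0, 1)]),
        ),
    ]
    corpus = AnnotatedCorpus(sents, frozenset({"X", "Y"}))
    rng = np.random.default_rng(5)
    space = EmbeddingSpace.from_mapping(
        {t: rng.normal(size=2) for t in ["ab", "cde", "f", "gg"]}
    )
    descriptor = InputDescriptor("W", word_space=space)
    cfg = TaggerConfig(
        batch_size=2, lstm_hidden_units=4, char_hidden_units=3,
        char_embedding_dim=3, dropout_rate=0.0, seed=seed,
    )
    labels = label_set({"X", "Y"})
    model = TaggerModel.create(
        cfg, labels, build_char_vocab(corpus), descriptor, np.random.default_rng(1)
    )
    return corpus, descriptor, model, labels


class TestCharacterEncoder:
    def test_single_character_token_dimension(self):
        _, _, model, _ = _tiny_setup()
        rep = encode_characters(model, ["f"])
        assert rep.shape == (1, 2 * model.config.char_hidden_units)

    def test_identical_surfaces_identical_representations(self):
        _, _, model, _ = _tiny_setup()
        rep = encode_characters(model, ["cde", "xx", "cde"])
        assert np.allclose(rep[0], rep[2])
        assert not np.allclose(rep[0], rep[1])

    def test_unknown_characters_use_reserved_embedding(self):
        _, _, model, _ = _tiny_setup()
        # neither character seen in training; both map to the unk symbol
        rep = encode_characters(model, ["ω", "ψ"])
        assert np.allclose(rep[0], rep[1])

    def test_shared_suffix_closer_after_training(self, small_run):
        """After training on a corpus whose Disease terms carry derivational
        suffixes, the character encoder places two suffix-sharing pseudo-
        words closer than a suffix-free word."""
        model = small_run.model
        # prefixes are matched pairwise so only the suffix signal differs
        rep = encode_characters(model, ["bodokitis", "natefitis", "natefipril"])
        sim_same_suffix = cosine_similarity(rep[0], rep[1])
        sim_other_suffix = cosine_similarity(rep[1], rep[2])
        assert sim_same_suffix > sim_other_suffix


class TestTokenInput:
    def test_dimensions_add(self):
        v = build_token_input(np.ones(6), np.zeros(4))
        assert v.shape == (10,)

    def test_oov_token_keeps_char_part(self):
        _, descriptor, model, _ = _tiny_setup()
        char = encode_characters(model, ["zzz"])[0]
        word = descriptor.vector("zzz", "zzz")  # OOV -> zero vector
        v = build_token_input(char, word)
        assert np.allclose(v[: len(char)], char)
        assert not v[len(char):].any()


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        """Full-model loss gradients agree with central differences."""
        corpus, descriptor, model, labels = _tiny_setup()
        li = {t: i for i, t in enumerate(labels)}
        sents = corpus.sentences
        wv = [
            np.stack([descriptor.vector(t.surface, t.lemma) for t in s.tokens])
            for s in sents
        ]
        gold = [[li[t] for t in spans_to_bio(s)] for s in sents]
        _, grads = batch_loss_and_grads(model, sents, wv, gold)
        params = model.parameters()
        rng = np.random.default_rng(2)
        eps = 1e-6
        for name, p in params.items():
            flat_idx = rng.choice(p.size, size=min(4, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = batch_loss_and_grads(model, sents, wv, gold)
                p[idx] = orig - eps
                lm, _ = batch_loss_and_grads(model, sents, wv, gold)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=5e-6), name


def _small_split(n_train=30, n_dev=10, seed=0):
    from clinner.synthetic_data import generate_dataset, profile_config

    cfg = profile_config(
        "A", seed=seed, sentences_per_part=(n_train, n_dev, 10),
        lexicon_size_per_type=8, ambiguity_rate=0.0,
    )
    return generate_dataset(cfg).split


def _small_descriptor(split, dim=10, seed=0):
    rng = np.random.default_rng(seed)
    vocab = {t.surface for s in split.train.sentences for t in s.tokens}
    space = EmbeddingSpace.from_mapping({w: rng.normal(size=dim) for w in sorted(vocab)})
    return InputDescriptor("W", word_space=space)


def _tiny_config(**kw):
    defaults = dict(
        batch_size=10, lstm_hidden_units=12, char_hidden_units=6,
        char_embedding_dim=6, max_epochs=3, seed=0,
    )
    defaults.update(kw)
    return TaggerConfig(**defaults)


class TestTraining:
    def test_early_stopping_rule(self, monkeypatch):
        """A strictly decreasing dev trace stops after 1 + patience epochs."""
        scripted = iter([50.0, 40.0, 30.0, 20.0, 10.0, 5.0])
        monkeypatch.setattr(nt, "_dev_f1", lambda model, corpus: next(scripted))
        split = _small_split(n_train=10)
        _, report = train(
            _tiny_config(patience=3, max_epochs=10),
            split, _small_descriptor(split), evaluate_test=False,
        )
        assert report.best_epoch == 1
        assert report.stopped_epoch == 4
        assert report.dev_f1_trace == [50.0, 40.0, 30.0, 20.0]

    def test_stopping_epoch_bounded_by_patience(self, small_run):
        r = small_run.report
        assert r.stopped_epoch <= r.best_epoch + small_run.model.config.patience

    def test_fixed_seed_identical_reports(self):
        split = _small_split()
        desc = _small_descriptor(split)
        reports = [
            train(_tiny_config(seed=7), split, desc, evaluate_test=False)[1]
            for _ in range(2)
        ]
        assert reports[0].dev_f1_trace == reports[1].dev_f1_trace
        assert reports[0].best_epoch == reports[1].best_epoch

    def test_dimension_mismatch_rejected_before_training(self):
        split = _small_split()
        desc = _small_descriptor(split, dim=10)
        with pytest.raises(ValueError, match="word_vector_dim"):
            train(_tiny_config(word_vector_dim=99), split, desc)

    def test_training_loss_decreases_initially(self):
        """Mean train-batch NLL is lower after two epochs than at start."""
        split = _small_split()
        desc = _small_descriptor(split)
        labels = label_set(split.entity_inventory)
        li = {t: i for i, t in enumerate(labels)}
        sents = split.train.sentences
        wv = [
            np.stack([desc.vector(t.surface, t.lemma) for t in s.tokens])
            for s in sents
        ]
        gold = [[li[t] for t in spans_to_bio(s)] for s in sents]

        def mean_loss(model):
            loss, _ = batch_loss_and_grads(model, sents, wv, gold)
            return loss

        cfg = _tiny_config(max_epochs=1, dropout_rate=0.0)
        model0 = TaggerModel.create(
            cfg, labels, build_char_vocab(split.train), desc,
            np.random.default_rng(cfg.seed),
        )
        initial = mean_loss(model0)
        model, _ = train(
            _tiny_config(max_epochs=2, dropout_rate=0.0), split, desc,
            evaluate_test=False,
        )
        assert mean_loss(model) < initial


class TestPredict:
    def test_idempotent(self, small_run):
        again = predict(small_run.model, small_run.split.test)
        assert again == small_run.test_pred

    def test_memorizes_training_data(self, small_run):
        report = score(
            small_run.split.train,
            predict(small_run.model, small_run.split.train),
            EXACT,
        )
        assert report.micro["f1"] >= 95.0

    def test_unseen_entity_in_indicative_context_is_tagged(self, small_run):
        """A held-out entity term placed in a strongly type-indicating
        context still receives the entity tag (context generalization)."""
        lex = small_run.result.lexicons
        etype = sorted(small_run.split.entity_inventory)[0]
        term = next(t for t in lex.heldout_terms[etype] if len(t.words) == 1)
        trigger = lex.triggers_pre[etype][0]
        filler = lex.fillers[0]
        sent = AnnotatedSentence(
            [Token(filler, filler), Token(trigger, trigger),
             Token(term.words[0], term.lemmas[0])],
            frozenset(),
        )
        probe = AnnotatedCorpus([sent], small_run.split.entity_inventory)
        tags = predict(small_run.model, probe)[0]
        assert tags[2] == f"B-{etype}"


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self):
        split = _small_split(n_train=10)
        desc = _small_descriptor(split)
        cfg = _tiny_config(max_epochs=1)
        best, table = grid_search([cfg], split, desc)
        assert best == cfg
        assert len(table) == 1

    def test_sabotaged_config_loses(self):
        split = _small_split(n_train=100, n_dev=20)
        desc = _small_descriptor(split)
        learning = dict(
            batch_size=20, lstm_hidden_units=32, char_hidden_units=16,
            char_embedding_dim=8, learning_rate=0.01, max_epochs=8, seed=0,
        )
        sabotaged = TaggerConfig(**{**learning, "learning_rate": 1e-12})
        normal = TaggerConfig(**learning)
        best, table = grid_search([sabotaged, normal], split, desc)
        assert best == normal
        assert table["dev_f1"].idxmax() == 1

    def test_winner_has_highest_recorded_score(self):
        split = _small_split()
        desc = _small_descriptor(split)
        grid = [
            _tiny_config(batch_size=5, max_epochs=2),
            _tiny_config(batch_size=10, max_epochs=2),
            _tiny_config(lstm_hidden_units=8, max_epochs=2),
            _tiny_config(learning_rate=0.001, max_epochs=2),
        ]
        best, table = grid_search(grid, split, desc)
        assert table.loc[table.index[grid.index(best)], "dev_f1"] == table["dev_f1"].max()

    def test_empty_grid_rejected(self):
        split = _small_split(n_train=10)
        with pytest.raises(ValueError):
            grid_search([], split, _small_descriptor(split))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_run):
        save_model(small_run.model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert loaded.labels == small_run.model.labels
        assert predict(loaded, small_run.split.test) == small_run.test_pred


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TaggerConfig(dropout_rate=1.0)
    with pytest.raises(ValueError):
        TaggerConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TaggerConfig(batch_size=0)
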