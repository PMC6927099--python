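"""Error-source vocabularies, outcome grouping and attribution tables."""

import math

import numpy as np
import pytest

from clinner.corpus_io import (
    AnnotatedCorpus,
    AnnotatedSentence,
    EntityMention,
    Token,
    spans_to_bio,
)
from clinner.error_analysis import (
    ErrorSourceSets,
    TokenOutcomeGroups,
    compute_error_sources,
    entity_error_table,
    group_token_outcomes,
    token_error_table,
    unseen_correct_rate,
)
from clinner.evaluation import EXACT, EntityMatchResult, match_corpus
from clinner.synthetic_data import generate_dataset, generate_raw_corpus, profile_config


def _sentence(words, mentions=()):
    return AnnotatedSentence([Token(w, w) for w in words], frozenset(mentions))


class TestTokenOutcomeGroups:
    def test_single_correct_occurrence(self):
        groups = group_token_outcomes([["O"]], [["O"]], [["x"]])
        assert groups.always_correct == {"x"}

    def test_mixed_occurrences_go_to_both(self):
        groups = group_token_outcomes(
            [["B-X"], ["B-X"]], [["B-X"], ["O"]], [["w"], ["w"]]
        )
        assert groups.both == {"w"}
        assert not groups.always_correct and not groups.always_incorrect

    def test_partition_property_random(self):
        rng = np.random.default_rng(0)
        tags = ["O", "B-X", "I-X"]
        for _ in range(20):
            n_sent = int(rng.integers(1, 6))
            tokens, gold, pred = [], [], []
            for _ in range(n_sent):
                n = int(rng.integers(1, 8))
                tokens.append([f"t{rng.integers(6)}" for _ in range(n)])
                gold.append([tags[rng.integers(3)] for _ in range(n)])
                pred.append([tags[rng.integers(3)] for _ in range(n)])
            groups = group_token_outcomes(gold, pred, tokens)
            observed = {t for sent in tokens for t in sent}
            parts = [groups.always_correct, groups.always_incorrect, groups.both]
            assert frozenset().union(*parts) == observed
            assert sum(map(len, parts)) == len(observed)

    def test_alignment_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_token_outcomes([["O", "O"]], [["O"]], [["a", "b"]])


class TestErrorSources:
    def test_ootv_empty_when_all_test_tokens_in_train(self):
        train = AnnotatedCorpus([_sentence(["a", "b"])], frozenset({"X"}))
        test = AnnotatedCorpus([_sentence(["b", "a"])], frozenset({"X"}))
        sources = compute_error_sources(train, {"a", "b"}, test)
        assert sources.ootv == frozenset()
        assert sources.ooev == frozenset()

    def test_ambiguously_annotated_token(self):
        # "head" is a Body part on its own but sits inside a Disorder
        # elsewhere: two distinct gold tags => ambiguously annotated
        train = AnnotatedCorpus(
            [
                _sentence(["the", "head"], [EntityMention("Body part", 1, 2)]),
                _sentence(["head", "ache"], [EntityMention("Disorder", 0, 2)]),
            ],
            frozenset({"Body part", "Disorder"}),
        )
        test = AnnotatedCorpus([_sentence(["head"])], frozenset(train.entity_inventory))
        sources = compute_error_sources(train, {"head"}, test)
        assert "head" in sources.aav

    def test_nea_sequences(self):
        # "neck pain" is a Finding once and plain text once
        train = AnnotatedCorpus(
            [
                _sentence(["neck", "pain"], [EntityMention("Finding", 0, 2)]),
                _sentence(["no", "neck", "pain", "today"]),
            ],
            frozenset({"Finding"}),
        )
        test = AnnotatedCorpus([_sentence(["x"])], frozenset({"Finding"}))
        sources = compute_error_sources(train, set(), test)
        assert ("neck", "pain") in sources.nea

    def test_sources_independent_of_predictions(self, small_run):
        split = small_run.split
        vocab = small_run.space.vocabulary
        a = compute_error_sources(split.train, vocab, split.test)
        b = compute_error_sources(split.train, vocab, split.test)
        assert (a.ooev, a.ootv, a.aav, a.nea) == (b.ooev, b.ootv, b.aav, b.nea)

    def test_clean_generator_run_has_empty_sources(self):
        """With no ambiguity, no unseen test terms and full-overlap
        embeddings, AAV, OOTV and OOEV are all empty."""
        cfg = profile_config(
            "A", seed=6, ambiguity_rate=0.0, target_test_oov_fraction=0.0,
            misspelling_rate=0.0, abbreviation_rate=0.0,
            sentences_per_part=(400, 40, 40),
        )
        res = generate_dataset(cfg)
        raw_vocab = {t for s in generate_raw_corpus(cfg, 1.0) for t in s}
        sources = compute_error_sources(res.split.train, raw_vocab, res.split.test)
        assert sources.aav == frozenset()
        assert sources.ooev == frozenset()
        assert sources.ootv == frozenset()


class TestTokenErrorTable:
    def _groups(self, correct, incorrect, both=()):
        return TokenOutcomeGroups(
            frozenset(correct), frozenset(incorrect), frozenset(both)
        )

    def _sources(self, ooev=(), ootv=(), aav=()):
        return ErrorSourceSets(
            frozenset(ooev), frozenset(ootv), frozenset(aav), frozenset()
        )

    def test_group_contained_in_source_is_100(self):
        table = token_error_table(
            self._groups(["a", "b"], []), self._sources(ootv=["a", "b", "c"])
        )
        assert table.loc["Correct", "OOTV"] == 100.0

    def test_disjoint_group_and_source_is_0(self):
        table = token_error_table(
            self._groups(["a"], []), self._sources(ooev=["z"])
        )
        assert table.loc["Correct", "OOEV"] == 0.0

    def test_hand_counted_percentage(self):
        incorrect = [f"w{i}" for i in range(10)]
        table = token_error_table(
            self._groups([], incorrect), self._sources(ootv=incorrect[:6])
        )
        assert table.loc["Incorrect", "OOTV"] == pytest.approx(60.00)

    def test_empty_group_is_undefined_not_zero(self):
        table = token_error_table(self._groups(["a"], []), self._sources())
        assert math.isnan(table.loc["Both", "OOTV"])

    def test_cells_bounded(self, small_run):
        gold = [spans_to_bio(s) for s in small_run.split.test.sentences]
        tokens = [s.surfaces for s in small_run.split.test.sentences]
        groups = group_token_outcomes(gold, small_run.test_pred, tokens)
        sources = compute_error_sources(
            small_run.split.train, small_run.space.vocabulary, small_run.split.test
        )
        table = token_error_table(groups, sources)
        vals = table.values[~np.isnan(table.values)]
        assert ((vals >= 0) & (vals <= 100)).all()
        assert list(table.columns) == ["OOEV", "AAV", "OOTV"]


class TestEntityErrorTable:
    def _fixture(self):
        train = AnnotatedCorpus(
            [_sentence(["known", "drug"], [EntityMention("Drug", 0, 2)])],
            frozenset({"Drug"}),
        )
        # 4 test sentences, gold has no mentions, predictions create 4 FP:
        # 3 with token sequences unseen as training mentions, 1 seen
        test = AnnotatedCorpus(
            [
                _sentence(["known", "drug"]),
                _sentence(["fresh1"]),
                _sentence(["fresh2"]),
                _sentence(["fresh3"]),
            ],
            frozenset({"Drug"}),
        )
        predicted = [["B-Drug", "I-Drug"], ["B-Drug"], ["B-Drug"], ["B-Drug"]]
        result = match_corpus(test, predicted, EXACT)
        sources = compute_error_sources(train, set(), test)
        return result, sources, test, train

    def test_fp_ootv_hand_count(self):
        result, sources, test, train = self._fixture()
        table = entity_error_table(result, sources, test, train)
        assert table.loc["FP", "OOTV"] == pytest.approx(75.00)

    def test_empty_class_is_undefined(self):
        result, sources, test, train = self._fixture()
        assert not result.tp
        table = entity_error_table(result, sources, test, train)
        assert math.isnan(table.loc["TP", "NEA"])

    def test_all_unseen_false_negatives(self):
        train = AnnotatedCorpus(
            [_sentence(["aaa"], [EntityMention("Drug", 0, 1)])], frozenset({"Drug"})
        )
        test = AnnotatedCorpus(
            [_sentence(["bbb"], [EntityMention("Drug", 0, 1)])], frozenset({"Drug"})
        )
        result = match_corpus(test, [["O"]], EXACT)
        sources = compute_error_sources(train, set(), test)
        table = entity_error_table(result, sources, test, train)
        assert table.loc["FN", "OOTV"] == 100.0
        assert table.loc["FN", "NEA"] == 0.0  # no non-entity annotations

    def test_table_layout(self):
        result, sources, test, train = self._fixture()
        table = entity_error_table(result, sources, test, train)
        assert list(table.index) == ["TP", "FP", "FN"]
        assert list(table.columns) == ["NEA", "AAV", "OOTV"]


class TestUnseenCorrectRate:
    def test_all_seen_gives_zero(self):
        train = AnnotatedCorpus(
            [_sentence(["aspirin"], [EntityMention("Drug", 0, 1)])], frozenset({"Drug"})
        )
        test = AnnotatedCorpus(
            [_sentence(["aspirin"], [EntityMention("Drug", 0, 1)])], frozenset({"Drug"})
        )
        result = match_corpus(test, [["B-Drug"]], EXACT)
        assert unseen_correct_rate(train, result, test) == 0.0

    def test_empty_tp_undefined(self):
        train = AnnotatedCorpus([_sentence(["a"])], frozenset({"Drug"}))
        test = AnnotatedCorpus([_sentence(["a"])], frozenset({"Drug"}))
        result = match_corpus(test, [["O"]], EXACT)
        assert math.isnan(unseen_correct_rate(train, result, test))

    def test_generalization_on_synthetic_run(self, small_run):
        """With 30% of test mentions unseen in training and a well-trained
        model, some correctly tagged mentions must be novel."""
        result = match_corpus(small_run.split.test, small_run.test_pred, EXACT)
        rate = unseen_correct_rate(small_run.split.train, result, small_run.split.test)
        assert 0.0 < rate <= 1.0
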