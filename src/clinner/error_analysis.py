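"""Error-source attribution for NER output.

Token types observed in the test set are grouped by aggregate outcome —
always tagged correctly, always incorrectly, or both — and compared
against error-source vocabularies computed from the training data and
the embedding vocabulary alone:

* OOEV — token types absent from the embedding vocabulary (they enter
  the network with a zero word vector);
* OOTV — token types absent from the training data;
* AAV  — token types annotated with more than one distinct BIO tag in
  training (ambiguously-annotated vocabulary);
* NEA  — non-entity annotations: token sequences that occur in training
  both as an entity mention and as plain (non-entity) text.

Token-level correctness means the full BIO tag, including the B/I
distinction, matches gold.  Percentages are tabulated per outcome group
(token level) and per exact-match outcome class TP/FP/FN (entity
level); source sets overlap, so rows need not sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus_io import AnnotatedCorpus, spans_to_bio
from .evaluation import EntityMatchResult

__all__ = [
    "TokenOutcomeGroups",
    "ErrorSourceSets",
    "group_token_outcomes",
    "compute_error_sources",
    "token_error_table",
    "entity_error_table",
    "unseen_correct_rate",
]

UNDEFINED = float("nan")


@dataclass
class TokenOutcomeGroups:
    """Partition of observed test token types by aggregate correctness."""

    always_correct: frozenset[str]
    always_incorrect: frozenset[str]
    both: frozenset[str]

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "Correct": self.always_correct,
            "Incorrect": self.always_incorrect,
            "Both": self.both,
        }


@dataclass
class ErrorSourceSets:
    """Error-source vocabularies, computed from training data plus the
    embedding vocabulary only (never from test predictions)."""

    ooev: frozenset[str]
    ootv: frozenset[str]
    aav: frozenset[str]
    nea: frozenset[tuple[str, ...]]  # token sequences

    def token_sets(self) -> dict[str, frozenset[str]]:
        return {"OOEV": self.ooev, "AAV": self.aav, "OOTV": self.ootv}


def group_token_outcomes(
    gold_tags: Sequence[Sequence[str]],
    predicted_tags: Sequence[Sequence[str]],
    tokens: Sequence[Sequence[str]],
) -> TokenOutcomeGroups:
    """Sort each observed token type into correct / incorrect / both."""
    if not (len(gold_tags) == len(predicted_tags) == len(tokens)):
        raise ValueError("inputs must have the same number of sentences")
    correct: dict[str, set[bool]] = {}
    for g_sent, p_sent, t_sent in zip(gold_tags, predicted_tags, tokens):
        if not (len(g_sent) == len(p_sent) == len(t_sent)):
            raise ValueError("sentence lengths do not align")
        for g, p, tok in zip(g_sent, p_sent, t_sent):
            correct.setdefault(tok, set()).add(g == p)
    always_c, always_i, both = set(), set(), set()
    for tok, outcomes in correct.items():
        if outcomes == {True}:
            always_c.add(tok)
        elif outcomes == {False}:
            always_i.add(tok)
        else:
            both.add(tok)
    return TokenOutcomeGroups(
        frozenset(always_c), frozenset(always_i), frozenset(both)
    )


def _mention_sequences(corpus: AnnotatedCorpus) -> set[tuple[str, ...]]:
    out = set()
    for sent in corpus.sentences:
        for m in sent.mentions:
            out.add(tuple(sent.surfaces[m.start : m.end]))
    return out


def compute_error_sources(
    train: AnnotatedCorpus,
    embedding_vocabulary: set[str],
    test: AnnotatedCorpus,
) -> ErrorSourceSets:
    """Build the OOEV/OOTV/AAV/NEA sets.

    OOEV and OOTV are subsets of the test token types; AAV is the set of
    token types carrying more than one distinct gold BIO tag in training
    (the O tag counts, so a word seen both inside an entity and as plain
    text is ambiguous); NEA holds training mention token sequences that
    also occur uncovered by any mention.
    """
    test_types = test.token_types
    train_types = train.token_types
    ooev = frozenset(t for t in test_types if t not in embedding_vocabulary)
    ootv = frozenset(t for t in test_types if t not in train_types)

    tags_seen: dict[str, set[str]] = {}
    for sent in train.sentences:
        for tok, tag in zip(sent.tokens, spans_to_bio(sent)):
            tags_seen.setdefault(tok.surface, set()).add(tag)
    aav = frozenset(t for t, tags in tags_seen.items() if len(tags) > 1)

    mention_seqs = _mention_sequences(train)
    nea = set()
    for sent in train.sentences:
        surf = sent.surfaces
        covered = {
            (m.start, m.end) for m in sent.mentions
        }
        for seq in mention_seqs:
            k = len(seq)
            for i in range(len(surf) - k + 1):
                if tuple(surf[i : i + k]) == seq and (i, i + k) not in covered:
                    nea.add(seq)
    return ErrorSourceSets(ooev, ootv, aav, frozenset(nea))


def token_error_table(
    groups: TokenOutcomeGroups, sources: ErrorSourceSets
) -> pd.DataFrame:
    """Percentage of each outcome group found in each token-level error
    source (rows: Correct/Incorrect/Both; columns: OOEV/AAV/OOTV).

    Sources overlap, so rows need not sum to 100.  Cells for an empty
    group are undefined (NaN), not zero.
    """
    rows = {}
    for gname, group in groups.as_dict().items():
        row = {}
        for sname, source in sources.token_sets().items():
            if not group:
                row[sname] = UNDEFINED
            else:
                row[sname] = 100.0 * len(group & source) / len(group)
        rows[gname] = row
    return pd.DataFrame.from_dict(rows, orient="index")[["OOEV", "AAV", "OOTV"]]


def _entity_sequence(
    corpus: AnnotatedCorpus, sent_idx: int, start: int, end: int
) -> tuple[str, ...]:
    return tuple(corpus.sentences[sent_idx].surfaces[start:end])


def entity_error_table(
    match_result: EntityMatchResult,
    sources: ErrorSourceSets,
    corpus: AnnotatedCorpus,
    train: AnnotatedCorpus,
) -> pd.DataFrame:
    """Percentage of TP/FP/FN entities attributable to each entity-level
    error source (columns NEA/AAV/OOTV).

    An entity belongs to NEA if its surface token sequence is a
    non-entity annotation sequence of the training data; to AAV if any
    of its tokens is ambiguously annotated; to OOTV if its surface
    sequence never occurs as a training mention of any type.  FP
    membership is judged on the predicted mention's tokens, FN on the
    gold mention's.
    """
    train_mention_seqs = _mention_sequences(train)
    classes = {"TP": match_result.tp, "FP": match_result.fp, "FN": match_result.fn}
    rows = {}
    for cname, items in classes.items():
        if not items:
            rows[cname] = {"NEA": UNDEFINED, "AAV": UNDEFINED, "OOTV": UNDEFINED}
            continue
        n = len(items)
        nea = aav = ootv = 0
        for sent_idx, m in items:
            seq = _entity_sequence(corpus, sent_idx, m.start, m.end)
            if seq in sources.nea:
                nea += 1
            if any(tok in sources.aav for tok in seq):
                aav += 1
            if seq not in train_mention_seqs:
                ootv += 1
        rows[cname] = {
            "NEA": 100.0 * nea / n,
            "AAV": 100.0 * aav / n,
            "OOTV": 100.0 * ootv / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["NEA", "AAV", "OOTV"]]


def unseen_correct_rate(
    train: AnnotatedCorpus,
    match_result: EntityMatchResult,
    corpus: AnnotatedCorpus,
) -> float:
    """Fraction of exact-match true positives whose (type, token
    sequence) pair never occurs as a training mention — the measure of
    generalization to unseen entities.  Undefined (NaN) when there are
    no true positives.
    """
    if not match_result.tp:
        return UNDEFINED
    train_pairs = {
        (m.entity_type, tuple(s.surfaces[m.start : m.end]))
        for s in train.sentences
        for m in s.mentions
    }
    unseen = sum(
        1
        for sent_idx, m in match_result.tp
        if (m.entity_type, _entity_sequence(corpus, sent_idx, m.start, m.end))
        not in train_pairs
    )
    return unseen / len(match_result.tp)
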