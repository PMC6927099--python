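"""Annotated-corpus data model, BIO codec, and CoNLL-style column file I/O.

A corpus is a sequence of sentences; each sentence is a sequence of
(surface, lemma) tokens plus a set of typed, non-overlapping entity
mentions given as token spans.  Mentions are serialised to and from the
IOB2 ("BIO") per-token tagging scheme: the first token of a mention is
tagged ``B-<type>``, subsequent tokens ``I-<type>``, and every other
token ``O``.

The on-disk dialect is CoNLL-2003-like: UTF-8, one token per line with
tab-separated columns ``TOKEN<TAB>LEMMA<TAB>BIOTAG``, and a blank line
between sentences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Token",
    "EntityMention",
    "AnnotatedSentence",
    "AnnotatedCorpus",
    "DataSplit",
    "CorpusFormatError",
    "spans_to_bio",
    "bio_to_spans",
    "read_corpus",
    "write_corpus",
    "corpus_stats",
]

OUTSIDE = "O"


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid tag sequences."""


@dataclass(frozen=True)
class Token:
    """A single token: surface form plus its lemma.

    ``characters`` is derived from the surface form (one element per
    unicode code point); it feeds the character-level encoder.
    """

    surface: str
    lemma: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")

    @property
    def characters(self) -> tuple[str, ...]:
        return tuple(self.surface)


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed contiguous token span, 0-based half-open [start, end)."""

    entity_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid mention span [{self.start}, {self.end})"
            )

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


def _check_mentions(mentions: Iterable[EntityMention], n_tokens: int) -> None:
    ms = sorted(mentions, key=lambda m: (m.start, m.end))
    for m in ms:
        if m.end > n_tokens:
            raise ValueError(
                f"mention [{m.start}, {m.end}) exceeds sentence length {n_tokens}"
            )
    for a, b in zip(ms, ms[1:]):
        if a.overlaps(b):
            raise CorpusFormatError(
                f"overlapping mentions {a} and {b} are not supported"
            )


@dataclass
class AnnotatedSentence:
    tokens: list[Token]
    mentions: frozenset[EntityMention] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.tokens = list(self.tokens)
        self.mentions = frozenset(self.mentions)
        _check_mentions(self.mentions, len(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]


@dataclass
class AnnotatedCorpus:
    sentences: list[AnnotatedSentence]
    entity_inventory: frozenset[str]

    def __post_init__(self) -> None:
        self.sentences = list(self.sentences)
        self.entity_inventory = frozenset(self.entity_inventory)
        for s in self.sentences:
            for m in s.mentions:
                if m.entity_type not in self.entity_inventory:
                    raise ValueError(
                        f"mention type {m.entity_type!r} not in inventory "
                        f"{sorted(self.entity_inventory)}"
                    )

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    @property
    def token_types(self) -> set[str]:
        return {t.surface for s in self.sentences for t in s.tokens}


@dataclass
class DataSplit:
    """Train/dev/test partition with a shared entity inventory."""

    train: AnnotatedCorpus
    dev: AnnotatedCorpus
    test: AnnotatedCorpus

    def __post_init__(self) -> None:
        inv = self.train.entity_inventory
        if not (inv == self.dev.entity_inventory == self.test.entity_inventory):
            raise ValueError("entity inventories differ across split parts")

    @property
    def entity_inventory(self) -> frozenset[str]:
        return self.train.entity_inventory

    def parts(self) -> dict[str, AnnotatedCorpus]:
        return {"Train": self.train, "Dev": self.dev, "Test": self.test}


def label_set(inventory: Iterable[str]) -> list[str]:
    """Ordered BIO tag alphabet: O first, then B-/I- per sorted type."""
    tags = [OUTSIDE]
    for t in sorted(set(inventory)):
        tags.extend([f"B-{t}", f"I-{t}"])
    return tags


def spans_to_bio(sentence: AnnotatedSentence) -> list[str]:
    """Encode a sentence's mentions as one IOB2 tag per token."""
    _check_mentions(sentence.mentions, len(sentence.tokens))
    tags = [OUTSIDE] * len(sentence.tokens)
    for m in sorted(sentence.mentions):
        tags[m.start] = f"B-{m.entity_type}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.entity_type}"
    return tags


def _parse_tag(tag: str) -> tuple[str, str | None]:
    if tag == OUTSIDE:
        return OUTSIDE, None
    if len(tag) > 2 and tag[1] == "-" and tag[0] in ("B", "I"):
        return tag[0], tag[2:]
    raise CorpusFormatError(f"unknown BIO tag {tag!r}")


def bio_to_spans(tags: Sequence[str]) -> frozenset[EntityMention]:
    """Decode an IOB2 tag sequence into a set of entity mentions.

    An ``I-X`` not preceded by ``B-X`` or ``I-X`` (possible in raw model
    output) is repaired to ``B-X`` before decoding — standard IOB2
    repair, making the decoder total on {O, B-*, I-*} sequences.
    """
    mentions: list[EntityMention] = []
    cur_type: str | None = None
    cur_start = 0
    for i, tag in enumerate(tags):
        marker, etype = _parse_tag(tag)
        if marker == "I" and etype != cur_type:
            marker = "B"  # orphan-I repair
        if cur_type is not None and marker != "I":
            mentions.append(EntityMention(cur_type, cur_start, i))
            cur_type = None
        if marker == "B":
            cur_type, cur_start = etype, i
    if cur_type is not None:
        mentions.append(EntityMention(cur_type, cur_start, len(tags)))
    return frozenset(mentions)


def write_corpus(corpus: AnnotatedCorpus, path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    for sent in corpus.sentences:
        tags = spans_to_bio(sent)
        for tok, tag in zip(sent.tokens, tags):
            lines.append(f"{tok.surface}\t{tok.lemma}\t{tag}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def read_corpus(
    path: str | Path, entity_inventory: Iterable[str] | None = None
) -> AnnotatedCorpus:
    """Read a column-format corpus file.

    If ``entity_inventory`` is None it is inferred from the tags present.
    Malformed lines are rejected with the offending line number.
    """
    path = Path(path)
    sentences: list[AnnotatedSentence] = []
    tokens: list[Token] = []
    tags: list[str] = []

    def flush() -> None:
        if tokens:
            sentences.append(
                AnnotatedSentence(list(tokens), bio_to_spans(tags))
            )
            tokens.clear()
            tags.clear()

    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").split("\n"), start=1
    ):
        if not line.strip():
            flush()
            continue
        cols = line.rstrip("\r").split("\t")
        if len(cols) != 3:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, "
                f"got {len(cols)}"
            )
        surface, lemma, tag = cols
        _parse_tag(tag)  # validate early, with the line number at hand
        tokens.append(Token(surface, lemma))
        tags.append(tag)
    flush()

    if entity_inventory is None:
        entity_inventory = {
            m.entity_type for s in sentences for m in s.mentions
        }
    return AnnotatedCorpus(sentences, frozenset(entity_inventory))


def corpus_stats(split: DataSplit) -> pd.DataFrame:
    """Mention counts per entity type and split part, plus an All row.

    Layout mirrors the usual corpus-description table: one row per
    entity type (sorted), columns Train/Dev/Test.
    """
    types = sorted(split.entity_inventory)
    data = {}
    for part_name, corpus in split.parts().items():
        counts = dict.fromkeys(types, 0)
        for sent in corpus.sentences:
            for m in sent.mentions:
                counts[m.entity_type] += 1
        data[part_name] = [counts[t] for t in types] + [sum(counts.values())]
    return pd.DataFrame(data, index=types + ["All"])
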