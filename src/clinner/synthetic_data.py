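"""Synthetic clinical-style corpora for exercising the NER pipeline.

Real clinical corpora cannot be shared, so the pipeline is exercised on
generated pseudo-language corpora that reproduce the statistical
structure the experiments rely on:

* a small inventory of entity types, each with its own lexicon of one-
  to three-word terms whose words carry type-indicative suffixes (the
  subword signal a character encoder can exploit);
* noisy variants of entity terms — single-character-edit misspellings
  and abbreviations (initial-letter contractions such as "DM" for
  "diabetes mellitus") that share the lemma of the canonical form;
* a word-form → lemma map (some surfaces are inflected off their
  lemma);
* ambiguous token types that are annotated differently by context
  (entity in one sentence, plain text in another);
* a controllable fraction of test mentions whose surface form never
  occurs in training (the out-of-training-vocabulary stress);
* raw unannotated token streams whose vocabulary overlaps the annotated
  corpus by a controllable amount — overlap ≈ 1 emulates an in-domain
  health-record corpus, low overlap an out-of-domain general corpus.

All operations are deterministic given the config seed; each operation
draws from its own stream split from that seed, so enabling one option
does not perturb unrelated draws.

Two preset profiles mirror a two-language experimental setup: profile A
with entity types {Disease, Drug}, profile B with {Body part, Disorder,
Finding}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus_io import (
    AnnotatedCorpus,
    AnnotatedSentence,
    DataSplit,
    EntityMention,
    Token,
)

__all__ = [
    "GeneratorConfig",
    "Lexicons",
    "Term",
    "GenerationResult",
    "PROFILES",
    "profile_config",
    "build_lexicons",
    "generate_annotated_corpus",
    "generate_dataset",
    "generate_raw_corpus",
]


@dataclass(frozen=True)
class GeneratorConfig:
    entity_inventory: tuple[str, ...]
    lexicon_size_per_type: int = 30
    multiword_fraction: float = 0.3
    misspelling_rate: float = 0.1
    abbreviation_rate: float = 0.1
    ambiguity_rate: float = 0.05
    target_test_oov_fraction: float = 0.3
    sentences_per_part: tuple[int, int, int] = (300, 100, 100)
    context_vocab_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.entity_inventory:
            raise ValueError("entity inventory must be non-empty")
        for name in (
            "multiword_fraction", "misspelling_rate", "abbreviation_rate",
            "ambiguity_rate", "target_test_oov_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lexicon_size_per_type < 1 or self.context_vocab_size < 1:
            raise ValueError("counts must be positive")
        if any(n < 1 for n in self.sentences_per_part):
            raise ValueError("sentences_per_part counts must be positive")


PROFILES = {
    "A": ("Disease", "Drug"),
    "B": ("Body part", "Disorder", "Finding"),
}


def profile_config(profile: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Config for one of the preset pseudo-language profiles (A or B)."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    return replace(
        GeneratorConfig(entity_inventory=PROFILES[profile], seed=seed),
        **overrides,
    )


@dataclass(frozen=True)
class Term:
    """One lexicon entry: canonical words/lemmas plus optional variants."""

    words: tuple[str, ...]
    lemmas: tuple[str, ...]
    misspelled: tuple[str, ...] | None = None
    abbreviation: str | None = None

    def realisations(self) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        out = [(self.words, self.lemmas)]
        if self.misspelled is not None:
            out.append((self.misspelled, self.lemmas))
        if self.abbreviation is not None:
            out.append(((self.abbreviation,), ("_".join(self.lemmas),)))
        return out


@dataclass
class Lexicons:
    """Per-type term lists, context vocabulary and the lemma map."""

    terms: dict[str, list[Term]]
    train_terms: dict[str, list[Term]]  # eligible for train/dev mentions
    heldout_terms: dict[str, list[Term]]  # test-only (never in train)
    triggers_pre: dict[str, list[str]]  # type-indicative context words
    triggers_post: dict[str, list[str]]
    fillers: list[str]
    lemma_map: dict[str, str]


_CONSONANTS = "bdfgklmnprstv"
_VOWELS = "aeiou"

# type-indicative suffix pools (clinical-flavoured pseudo-morphology)
_SUFFIX_POOL = [
    ("itis", "osis", "algia"),
    ("olol", "icin", "pril"),
    ("derm", "kneb", "torax"),
    ("emia", "opati", "oma"),
    ("axel", "rygg", "fot"),
    ("smart", "frossa", "yrsel"),
]


def _syllable(rng: np.random.Generator) -> str:
    return _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[
        rng.integers(len(_VOWELS))
    ]


def _new_word(
    rng: np.random.Generator, used: set[str], suffix: str = ""
) -> str:
    for _ in range(1000):
        n_syll = int(rng.integers(2, 4))
        w = "".join(_syllable(rng) for _ in range(n_syll)) + suffix
        if w not in used:
            used.add(w)
            return w
    raise RuntimeError("could not generate a fresh word")


def _misspell(rng: np.random.Generator, word: str, used: set[str]) -> str | None:
    for _ in range(100):
        op = rng.integers(4)
        i = int(rng.integers(len(word)))
        if op == 0 and len(word) > 2:  # delete
            cand = word[:i] + word[i + 1 :]
        elif op == 1 and len(word) > 2 and i < len(word) - 1:  # swap
            cand = word[:i] + word[i + 1] + word[i] + word[i + 2 :]
        elif op == 2:  # substitute
            cand = word[:i] + _CONSONANTS[rng.integers(len(_CONSONANTS))] + word[i + 1 :]
        else:  # insert
            cand = word[:i] + _VOWELS[rng.integers(len(_VOWELS))] + word[i:]
        if cand != word and cand and cand not in used:
            used.add(cand)
            return cand
    return None


def _abbreviate(
    rng: np.random.Generator, words: tuple[str, ...], used: set[str]
) -> str | None:
    if len(words) > 1:
        cand = "".join(w[0] for w in words).upper()
    else:
        cand = words[0][:3].upper() + "."
    if cand in used:
        cand = cand + str(int(rng.integers(2, 10)))
        if cand in used:
            return None
    used.add(cand)
    return cand


def _rngs(config: GeneratorConfig) -> list[np.random.Generator]:
    """One independent stream per operation, split from the config seed."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def build_lexicons(config: GeneratorConfig) -> Lexicons:
    """Deterministically build per-type lexicons, variants and contexts."""
    rng = _rngs(config)[0]
    used: set[str] = set()
    lemma_map: dict[str, str] = {}

    def make_surface(lemma: str) -> str:
        # some word-forms are inflections of their lemma
        if rng.random() < 0.3:
            for suf in ("en", "er", "es", "s", "a"):
                cand = lemma + suf
                if cand not in used:
                    used.add(cand)
                    lemma_map[cand] = lemma
                    return cand
        lemma_map[lemma] = lemma
        return lemma

    types = list(config.entity_inventory)
    terms: dict[str, list[Term]] = {}
    for ti, etype in enumerate(sorted(types)):
        suffixes = _SUFFIX_POOL[ti % len(_SUFFIX_POOL)]
        entries: list[Term] = []
        for _ in range(config.lexicon_size_per_type):
            n_words = 1
            if rng.random() < config.multiword_fraction:
                n_words = int(rng.integers(2, 4))
            lemmas = tuple(
                _new_word(rng, used, suffixes[int(rng.integers(len(suffixes)))] if k == n_words - 1 else "")
                for k in range(n_words)
            )
            words = tuple(make_surface(l) for l in lemmas)
            misspelled = None
            if rng.random() < config.misspelling_rate:
                j = int(np.argmax([len(w) for w in words]))
                alt = _misspell(rng, words[j], used)
                if alt is not None:
                    misspelled = tuple(
                        alt if k == j else w for k, w in enumerate(words)
                    )
                    lemma_map[alt] = lemmas[j]
            abbreviation = None
            if rng.random() < config.abbreviation_rate:
                abbreviation = _abbreviate(rng, words, used)
                if abbreviation is not None:
                    if len(abbreviation) >= len(" ".join(words)):
                        used.discard(abbreviation)
                        abbreviation = None
                    else:
                        lemma_map[abbreviation] = "_".join(lemmas)
            entries.append(Term(words, lemmas, misspelled, abbreviation))
        terms[etype] = entries

    # held-out split for the unseen-in-training mention fraction
    train_terms: dict[str, list[Term]] = {}
    heldout_terms: dict[str, list[Term]] = {}
    for etype, entries in terms.items():
        n_held = 0
        if config.target_test_oov_fraction > 0:
            n_held = max(
                2, round(config.target_test_oov_fraction * len(entries))
            )
        if n_held >= len(entries):
            raise ValueError(
                "lexicon_size_per_type too small for the requested "
                "target_test_oov_fraction"
            )
        order = rng.permutation(len(entries))
        heldout_terms[etype] = [entries[i] for i in order[:n_held]]
        train_terms[etype] = [entries[i] for i in order[n_held:]]

    triggers_pre: dict[str, list[str]] = {}
    triggers_post: dict[str, list[str]] = {}
    for etype in sorted(types):
        pre = [_new_word(rng, used) for _ in range(2)]
        post = [_new_word(rng, used)]
        for w in pre + post:
            lemma_map[w] = w
        triggers_pre[etype] = pre
        triggers_post[etype] = post
    fillers = [_new_word(rng, used) for _ in range(config.context_vocab_size)]
    for w in fillers:
        lemma_map[w] = w
    return Lexicons(
        terms, train_terms, heldout_terms,
        triggers_pre, triggers_post, fillers, lemma_map,
    )


@dataclass
class GenerationResult:
    split: DataSplit
    lexicons: Lexicons
    planted_counts: dict[str, dict[str, int]]  # part -> type -> count
    ambiguous_words: list[str]


def _realise(
    rng: np.random.Generator, term: Term
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    reals = term.realisations()
    if len(reals) > 1 and rng.random() < 0.25:
        return reals[int(rng.integers(1, len(reals)))]
    return reals[0]


def _tokens(
    surfaces: Sequence[str], lemma_map: dict[str, str]
) -> list[Token]:
    return [Token(s, lemma_map.get(s, s)) for s in surfaces]


def generate_dataset(config: GeneratorConfig) -> GenerationResult:
    """Generate a full train/dev/test split with bookkeeping.

    Each sentence is built from context templates: optional neutral
    fillers, a type-indicative trigger word, the entity term tokens,
    and an optional post-trigger.  About 10% of sentences carry no
    mention; about 20% carry two.  In the dev and test parts a quota of
    mentions equal to the target out-of-vocabulary fraction is drawn
    from held-out terms that never occur in train — from disjoint
    halves of the held-out pool, so selecting a model on dev does not
    expose the test part's unseen terms.
    """
    lex = build_lexicons(config)
    rng = _rngs(config)[1]
    types = sorted(config.entity_inventory)

    single_word_train = [
        (etype, t)
        for etype in types
        for t in lex.train_terms[etype]
        if len(t.words) == 1
    ]
    n_amb = round(config.ambiguity_rate * len(single_word_train))
    if config.ambiguity_rate > 0 and n_amb > 0 and not single_word_train:
        raise ValueError(
            "ambiguity requested but no single-word terms available "
            "(multiword_fraction too high)"
        )
    amb_idx = rng.permutation(len(single_word_train))[:n_amb]
    ambiguous_words = [single_word_train[i][1].words[0] for i in amb_idx]

    # dev and test parts both carry the unseen-in-train mention quota
    # (they emulate draws from the same record collection), but from
    # disjoint halves of the held-out pool so model selection on dev
    # never sees the test part's unseen terms
    heldout_by_part: dict[str, dict[str, list[Term]]] = {"dev": {}, "test": {}}
    for etype, pool in lex.heldout_terms.items():
        if len(pool) < 2:
            heldout_by_part["dev"][etype] = list(pool)
            heldout_by_part["test"][etype] = list(pool)
        else:
            order = rng.permutation(len(pool))
            half = len(pool) // 2
            heldout_by_part["dev"][etype] = [pool[i] for i in order[:half]]
            heldout_by_part["test"][etype] = [pool[i] for i in order[half:]]

    # round-robin queues ensure every train term occurs in the train part
    rr: dict[str, list[Term]] = {}

    def next_train_term(etype: str) -> Term:
        if not rr.get(etype):
            pool = list(lex.train_terms[etype])
            rng.shuffle(pool)
            rr[etype] = pool
        return rr[etype].pop()

    def filler_run(lo: int, hi: int, allow_ambiguous: bool) -> list[str]:
        n = int(rng.integers(lo, hi + 1))
        out = []
        for _ in range(n):
            if allow_ambiguous and ambiguous_words and rng.random() < 0.5:
                out.append(ambiguous_words[int(rng.integers(len(ambiguous_words)))])
            else:
                out.append(lex.fillers[int(rng.integers(len(lex.fillers)))])
        return out

    def build_sentence(part: str, oov_slots: list[bool]) -> tuple[AnnotatedSentence, list[str]]:
        """oov_slots: one flag per mention to plant (test part only)."""
        surfaces: list[str] = []
        mentions: list[EntityMention] = []
        planted: list[str] = []
        allow_amb = part in ("train", "test")
        if not oov_slots:  # mention-free sentence; may carry ambiguous words
            surfaces = filler_run(3, 6, allow_amb)
        else:
            surfaces.extend(filler_run(0, 2, False))
            for k, is_oov in enumerate(oov_slots):
                etype = types[int(rng.integers(len(types)))]
                if is_oov:
                    pool = heldout_by_part[part][etype]
                    term = pool[int(rng.integers(len(pool)))]
                elif part == "train":
                    term = next_train_term(etype)
                else:
                    pool = lex.train_terms[etype]
                    term = pool[int(rng.integers(len(pool)))]
                words, _ = _realise(rng, term)
                pre = lex.triggers_pre[etype]
                surfaces.append(pre[int(rng.integers(len(pre)))])
                start = len(surfaces)
                surfaces.extend(words)
                mentions.append(EntityMention(etype, start, start + len(words)))
                planted.append(etype)
                if rng.random() < 0.5:
                    post = lex.triggers_post[etype]
                    surfaces.append(post[int(rng.integers(len(post)))])
                if k < len(oov_slots) - 1:
                    surfaces.extend(filler_run(1, 2, False))
            surfaces.extend(filler_run(0, 2, allow_amb))
        return (
            AnnotatedSentence(_tokens(surfaces, lex.lemma_map), frozenset(mentions)),
            planted,
        )

    counts: dict[str, dict[str, int]] = {}
    corpora: dict[str, AnnotatedCorpus] = {}
    part_names = ("train", "dev", "test")
    for part, n_sent in zip(part_names, config.sentences_per_part):
        # per-sentence mention plan: ~10% empty, ~20% of the rest double
        plan: list[int] = []
        for _ in range(n_sent):
            if rng.random() < 0.1:
                plan.append(0)
            else:
                plan.append(2 if rng.random() < 0.2 else 1)
        total_slots = sum(plan)
        oov_flags = [False] * total_slots
        if part in ("dev", "test") and config.target_test_oov_fraction > 0:
            n_oov = round(config.target_test_oov_fraction * total_slots)
            for i in rng.permutation(total_slots)[:n_oov]:
                oov_flags[i] = True
        sentences = []
        part_counts = dict.fromkeys(types, 0)
        pos = 0
        for n_m in plan:
            sent, planted = build_sentence(part, oov_flags[pos : pos + n_m])
            pos += n_m
            sentences.append(sent)
            for etype in planted:
                part_counts[etype] += 1
        corpora[part] = AnnotatedCorpus(sentences, frozenset(types))
        counts[part] = part_counts

    split = DataSplit(corpora["train"], corpora["dev"], corpora["test"])
    return GenerationResult(split, lex, counts, ambiguous_words)


def generate_annotated_corpus(config: GeneratorConfig) -> DataSplit:
    """Generate a train/dev/test split (see :func:`generate_dataset`)."""
    return generate_dataset(config).split


def generate_raw_corpus(
    config: GeneratorConfig,
    overlap: float,
    n_sentences: int | None = None,
    unit: str = "word",
) -> list[list[str]]:
    """Unannotated token stream with controlled vocabulary overlap.

    The raw vocabulary shares a Jaccard overlap of ≈ ``overlap`` with
    the annotated split's vocabulary: overlap 1 emulates an in-domain
    corpus covering every annotated token type; overlap 0 a disjoint
    out-of-domain corpus.  Entity terms that survive the overlap filter
    co-occur with their usual trigger words, so distributional
    similarity between related terms remains learnable.  With
    ``unit="lemma"`` tokens are mapped through the lemma map.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    if unit not in ("word", "lemma"):
        raise ValueError("unit must be 'word' or 'lemma'")
    result = generate_dataset(config)
    lex = result.lexicons
    rng = _rngs(config)[2]

    vocab_ann = sorted(
        {t.surface for part in result.split.parts().values()
         for s in part.sentences for t in s.tokens}
    )
    # choose shared-subset and fresh-word counts so the Jaccard overlap
    # |keep| / (|vocab_ann| + n_out) equals the requested value
    V = len(vocab_ann)
    if overlap <= 0:
        n_out = round(0.5 * V)
        n_keep = 0
    else:
        n_out = round(V * min(0.5, (1.0 - overlap) / overlap))
        n_keep = min(V, round(overlap * (V + n_out)))
    keep = set(
        np.array(vocab_ann)[rng.permutation(V)[:n_keep]]
    )
    used = set(vocab_ann) | set(lex.lemma_map.values())
    out_domain = [_new_word(rng, used) for _ in range(n_out)]

    if n_sentences is None:
        n_sentences = 2 * sum(config.sentences_per_part)

    types = sorted(config.entity_inventory)

    def remap(surfaces: list[str]) -> list[str]:
        out = []
        for s in surfaces:
            if s in keep:
                out.append(s)
            elif out_domain:
                out.append(out_domain[int(rng.integers(len(out_domain)))])
        return out

    sentences: list[list[str]] = []
    for _ in range(n_sentences):
        if rng.random() < 0.15 and out_domain:
            toks = [
                out_domain[int(rng.integers(len(out_domain)))]
                for _ in range(int(rng.integers(3, 8)))
            ]
        else:
            etype = types[int(rng.integers(len(types)))]
            pool = lex.terms[etype]
            term = pool[int(rng.integers(len(pool)))]
            words, _ = _realise(rng, term)
            pre = lex.triggers_pre[etype]
            toks = remap(
                [lex.fillers[int(rng.integers(len(lex.fillers)))]]
                + [pre[int(rng.integers(len(pre)))]]
                + list(words)
                + [lex.fillers[int(rng.integers(len(lex.fillers)))]]
            )
        if toks:
            sentences.append(toks)

    # coverage pass: every kept and out-of-domain word must occur
    seen = {t for s in sentences for t in s}
    companions = sorted(keep | set(out_domain))
    for w in sorted((keep | set(out_domain)) - seen):
        toks = [w] + [
            companions[int(rng.integers(len(companions)))] for _ in range(3)
        ]
        sentences.append(toks)

    if unit == "lemma":
        sentences = [
            [lex.lemma_map.get(t, t) for t in s] for s in sentences
        ]
    return sentences
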