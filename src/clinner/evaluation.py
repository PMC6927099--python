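"""Entity-level scoring under exact and relaxed match criteria.

Exact match requires both the entity type and the token span to agree.
The relaxed ("partial") criteria loosen the span requirement to any
token overlap, the type requirement to "any type", or both.  Counting
follows the MUC-style convention: under a relaxed span, a predicted
mention is a true positive iff it overlaps at least one gold mention
satisfying the type criterion, and a gold mention is a false negative
iff no acceptable predicted mention overlaps it.  Precision is computed
over predicted mentions and recall over gold mentions, so relaxing the
criteria can only raise both.

Micro-averaged metrics pool TP/FP/FN counts over entity types.  All
reported metrics are on the 0-100 scale, displayed with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .corpus_io import (
    AnnotatedCorpus,
    EntityMention,
    bio_to_spans,
    label_set,
)

__all__ = [
    "MatchCriteria",
    "EXACT",
    "PARTIAL",
    "MetricsReport",
    "EntityMatchResult",
    "match_entities",
    "match_corpus",
    "score",
    "token_confusion",
    "CRITERIA_PRESETS",
]


@dataclass(frozen=True)
class MatchCriteria:
    """span_mode: exact | overlap; type_mode: exact | any."""

    span_mode: str = "exact"
    type_mode: str = "exact"

    def __post_init__(self) -> None:
        if self.span_mode not in ("exact", "overlap"):
            raise ValueError(f"bad span_mode {self.span_mode!r}")
        if self.type_mode not in ("exact", "any"):
            raise ValueError(f"bad type_mode {self.type_mode!r}")

    def mention_match(self, pred: EntityMention, gold: EntityMention) -> bool:
        if self.type_mode == "exact" and pred.entity_type != gold.entity_type:
            return False
        if self.span_mode == "exact":
            return (pred.start, pred.end) == (gold.start, gold.end)
        return pred.overlaps(gold)


EXACT = MatchCriteria("exact", "exact")
PARTIAL = MatchCriteria("overlap", "any")

CRITERIA_PRESETS = {
    "exact": EXACT,
    "partial": PARTIAL,
    "span-only": MatchCriteria("exact", "any"),
    "type-only": MatchCriteria("overlap", "exact"),
}


def _check_no_overlap(mentions: Sequence[EntityMention], side: str) -> None:
    ms = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(ms, ms[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping mentions within {side}: {a}, {b}")


def match_entities(
    gold: Sequence[EntityMention],
    predicted: Sequence[EntityMention],
    criteria: MatchCriteria = EXACT,
) -> tuple[frozenset[EntityMention], frozenset[EntityMention], frozenset[EntityMention]]:
    """Match one sentence's mentions; returns (TP, FP, FN) sets.

    TP are the predicted mentions accepted under the criteria, FP the
    remaining predicted mentions, FN the gold mentions with no
    acceptable prediction.  Under fully exact criteria this reduces to
    set intersection/difference on (type, start, end).
    """
    gold = list(gold)
    predicted = list(predicted)
    _check_no_overlap(gold, "gold")
    _check_no_overlap(predicted, "prediction")
    tp = frozenset(
        p for p in predicted if any(criteria.mention_match(p, g) for g in gold)
    )
    fp = frozenset(p for p in predicted if p not in tp)
    fn = frozenset(
        g for g in gold if not any(criteria.mention_match(p, g) for p in predicted)
    )
    return tp, fp, fn


@dataclass
class EntityMatchResult:
    """Corpus-level match outcome; mentions keyed by sentence index."""

    criteria: MatchCriteria
    tp: list[tuple[int, EntityMention]] = field(default_factory=list)
    fp: list[tuple[int, EntityMention]] = field(default_factory=list)
    fn: list[tuple[int, EntityMention]] = field(default_factory=list)
    n_gold: int = 0
    n_predicted: int = 0


def _predicted_mentions(
    corpus: AnnotatedCorpus, predicted_tags: Sequence[Sequence[str]]
) -> list[frozenset[EntityMention]]:
    if len(predicted_tags) != len(corpus.sentences):
        raise ValueError(
            f"{len(predicted_tags)} tag sequences for "
            f"{len(corpus.sentences)} sentences"
        )
    out = []
    for sent, tags in zip(corpus.sentences, predicted_tags):
        if len(tags) != len(sent):
            raise ValueError(
                f"tag sequence length {len(tags)} != sentence length {len(sent)}"
            )
        out.append(bio_to_spans(tags))
    return out


def match_corpus(
    gold: AnnotatedCorpus,
    predicted_tags: Sequence[Sequence[str]],
    criteria: MatchCriteria = EXACT,
) -> EntityMatchResult:
    """Decode predicted tags (with orphan-I repair) and match per sentence."""
    result = EntityMatchResult(criteria)
    for i, (sent, pred) in enumerate(
        zip(gold.sentences, _predicted_mentions(gold, predicted_tags))
    ):
        tp, fp, fn = match_entities(sorted(sent.mentions), sorted(pred), criteria)
        result.tp.extend((i, m) for m in sorted(tp))
        result.fp.extend((i, m) for m in sorted(fp))
        result.fn.extend((i, m) for m in sorted(fn))
        result.n_gold += len(sent.mentions)
        result.n_predicted += len(pred)
    return result


def _prf(tp: int, fp: int, fn: int, n_gold: int | None = None) -> dict:
    """P/R/F1 on the 0-100 scale; 0/0 reported as 0 with a flag."""
    undefined = []
    if tp + fp == 0:
        precision, matched_gold = 0.0, 0
        undefined.append("precision")
    else:
        precision = 100.0 * tp / (tp + fp)
    gold_total = n_gold if n_gold is not None else tp + fn
    if gold_total == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = 100.0 * (gold_total - fn) / gold_total
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "undefined": tuple(undefined),
    }


@dataclass
class MetricsReport:
    """Per-type and micro precision/recall/F1 (percent scale)."""

    criteria: MatchCriteria
    per_type: dict[str, dict]
    micro: dict

    def to_dataframe(self) -> pd.DataFrame:
        """Table with one row per entity type plus a micro 'Avg.' row."""
        rows = []
        for etype in sorted(self.per_type):
            d = self.per_type[etype]
            rows.append(
                {
                    "Entity": etype,
                    "Precision": round(d["precision"], 2),
                    "Recall": round(d["recall"], 2),
                    "F1-score": round(d["f1"], 2),
                }
            )
        rows.append(
            {
                "Entity": "Avg.",
                "Precision": round(self.micro["precision"], 2),
                "Recall": round(self.micro["recall"], 2),
                "F1-score": round(self.micro["f1"], 2),
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)


def score(
    gold: AnnotatedCorpus,
    predicted_tags: Sequence[Sequence[str]],
    criteria: MatchCriteria = EXACT,
) -> MetricsReport:
    """Corpus-level metrics from gold mentions and predicted BIO tags.

    Per-type rows are defined only under type-exact matching (each TP
    is then attributable to one type); with ``type_mode="any"`` only
    the micro row is populated.
    """
    result = match_corpus(gold, predicted_tags, criteria)
    micro = _prf(
        len(result.tp), len(result.fp), len(result.fn), result.n_gold
    )
    per_type: dict[str, dict] = {}
    if criteria.type_mode == "exact":
        for etype in sorted(gold.entity_inventory):
            tp = sum(1 for _, m in result.tp if m.entity_type == etype)
            fp = sum(1 for _, m in result.fp if m.entity_type == etype)
            fn = sum(1 for _, m in result.fn if m.entity_type == etype)
            n_gold = sum(
                1
                for s in gold.sentences
                for m in s.mentions
                if m.entity_type == etype
            )
            per_type[etype] = _prf(tp, fp, fn, n_gold)
    return MetricsReport(criteria, per_type, micro)


def token_confusion(
    gold_tags: Sequence[Sequence[str]] | Sequence[str],
    predicted_tags: Sequence[Sequence[str]] | Sequence[str],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gold x predicted count matrix over the BIO tag alphabet.

    Accepts flat tag sequences or per-sentence nested sequences (which
    must align sentence by sentence).
    """
    def flatten(seqs):
        if seqs and not isinstance(seqs[0], str):
            out = []
            for s in seqs:
                out.extend(s)
            return out
        return list(seqs)

    if gold_tags and not isinstance(gold_tags[0], str):
        if len(gold_tags) != len(predicted_tags) or any(
            len(g) != len(p) for g, p in zip(gold_tags, predicted_tags)
        ):
            raise ValueError("gold and predicted tag sequences do not align")
    g = flatten(gold_tags)
    p = flatten(predicted_tags)
    if len(g) != len(p):
        raise ValueError(f"length mismatch: {len(g)} gold vs {len(p)} predicted")
    if labels is None:
        types = {
            t[2:] for t in set(g) | set(p) if t != "O"
        }
        labels = label_set(types)
    mat = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for gt, pt in zip(g, p):
        mat.loc[gt, pt] += 1
    return mat
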