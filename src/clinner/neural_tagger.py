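"""Character-aware bidirectional LSTM sequence tagger with a CRF decoder.

Architecture (context encoder + tag decoder):

1. Each token's surface characters are run through a character-level
   bidirectional LSTM; the final forward and backward states are
   concatenated into a subword representation (captures suffixes such
   as "-itis"/"-algia" that mark clinical entity classes, and makes
   misspelled or unseen word-forms representable).
2. The character representation is concatenated with a fixed word-level
   input vector (a word embedding, lemma embedding, or one of their
   combinations; zero vector for out-of-vocabulary units).
3. A word-level bidirectional LSTM encodes sentence context; a linear
   projection produces per-token emission scores over the BIO tag set.
4. A linear-chain CRF scores whole tag sequences (emissions plus
   transition/start/stop scores); training maximises the conditional
   log-likelihood of the gold sequences and decoding is Viterbi.

Training uses mini-batch Adam with global-norm gradient clipping,
inverted dropout on the word-LSTM input, and early stopping on
development-set exact-match micro F1 with a configurable patience.
Everything (initialisation, shuffling, dropout) derives from the single
config seed, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import LSTM, Adam, clip_global_norm, reverse_padded, xavier
from .corpus_io import (
    AnnotatedCorpus,
    AnnotatedSentence,
    DataSplit,
    label_set,
    spans_to_bio,
)
from .crf import CRFParams, crf_marginals, viterbi_decode
from .embedding_spaces import (
    EmbeddingSpace,
    InputDescriptor,
    read_word2vec,
    write_word2vec,
)
from .evaluation import EXACT, MetricsReport, score

__all__ = [
    "TaggerConfig",
    "TaggerModel",
    "TrainReport",
    "encode_characters",
    "build_token_input",
    "train",
    "predict",
    "grid_search",
    "save_model",
    "load_model",
]

PAD_CHAR = 0
UNK_CHAR = 1


@dataclass
class TaggerConfig:
    """Hyperparameters; defaults follow the tuned values for this
    architecture (300 LSTM hidden units, 100 character hidden units,
    learning rate 0.005, dropout 0.5, character embedding dim 100,
    batch size 30, early-stopping patience 3).
    """

    batch_size: int = 30
    lstm_hidden_units: int = 300
    char_hidden_units: int = 100
    learning_rate: float = 0.005
    dropout_rate: float = 0.5
    char_embedding_dim: int = 100
    word_vector_dim: int | None = None  # inferred from the input descriptor
    patience: int = 3
    max_epochs: int = 100
    min_epochs: int = 1  # burn-in before early stopping may trigger
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "batch_size", "lstm_hidden_units", "char_hidden_units",
            "char_embedding_dim", "patience", "max_epochs", "min_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainReport:
    dev_f1_trace: list[float]
    best_epoch: int
    stopped_epoch: int
    test_metrics: MetricsReport | None = None

    @property
    def best_dev_f1(self) -> float:
        return self.dev_f1_trace[self.best_epoch - 1]


@dataclass
class TaggerModel:
    config: TaggerConfig
    labels: list[str]
    char_vocab: dict[str, int]
    descriptor: InputDescriptor
    char_embed: np.ndarray = field(repr=False, default=None)
    char_fwd: LSTM = None
    char_bwd: LSTM = None
    word_fwd: LSTM = None
    word_bwd: LSTM = None
    proj_W: np.ndarray = field(repr=False, default=None)
    proj_b: np.ndarray = field(repr=False, default=None)
    crf: CRFParams = None

    @classmethod
    def create(
        cls,
        config: TaggerConfig,
        labels: Sequence[str],
        char_vocab: dict[str, int],
        descriptor: InputDescriptor,
        rng: np.random.Generator,
    ) -> "TaggerModel":
        d_c = config.char_embedding_dim
        h_c = config.char_hidden_units
        h_w = config.lstm_hidden_units
        d_in = 2 * h_c + descriptor.dimension
        L = len(labels)
        n_chars = max(char_vocab.values()) + 1
        model = cls(
            config=config,
            labels=list(labels),
            char_vocab=dict(char_vocab),
            descriptor=descriptor,
            char_embed=rng.uniform(-0.5, 0.5, size=(n_chars, d_c))
            / np.sqrt(d_c),
            char_fwd=LSTM.create(rng, d_c, h_c),
            char_bwd=LSTM.create(rng, d_c, h_c),
            word_fwd=LSTM.create(rng, d_in, h_w),
            word_bwd=LSTM.create(rng, d_in, h_w),
            proj_W=xavier(rng, 2 * h_w, L),
            proj_b=np.zeros(L),
            crf=CRFParams.zeros(L),
        )
        model.char_embed[PAD_CHAR] = 0.0
        return model

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"char_embed": self.char_embed}
        params.update(self.char_fwd.params("char_fwd"))
        params.update(self.char_bwd.params("char_bwd"))
        params.update(self.word_fwd.params("word_fwd"))
        params.update(self.word_bwd.params("word_bwd"))
        params.update(
            {
                "proj.W": self.proj_W,
                "proj.b": self.proj_b,
                "crf.trans": self.crf.transitions,
                "crf.start": self.crf.start,
                "crf.stop": self.crf.stop,
            }
        )
        return params

    def char_ids(self, surface: str) -> list[int]:
        return [self.char_vocab.get(ch, UNK_CHAR) for ch in surface]


def build_char_vocab(corpus: AnnotatedCorpus) -> dict[str, int]:
    """Character inventory of the training part; 0 = pad, 1 = unknown."""
    chars = sorted({ch for s in corpus.sentences for t in s.tokens for ch in t.surface})
    return {ch: i + 2 for i, ch in enumerate(chars)}


# ---------------------------------------------------------------------------
# forward / backward machinery
# ---------------------------------------------------------------------------


def _char_batch(
    model: TaggerModel, surfaces: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ids, mask, lengths) for a flat list of token surfaces."""
    lengths = np.array([len(s) for s in surfaces], dtype=np.int64)
    maxlen = lengths.max()
    ids = np.zeros((len(surfaces), maxlen), dtype=np.int64)
    mask = np.zeros((len(surfaces), maxlen))
    for i, s in enumerate(surfaces):
        cid = model.char_ids(s)
        ids[i, : len(cid)] = cid
        mask[i, : len(cid)] = 1.0
    return ids, mask, lengths


def _encode_chars_batch(model: TaggerModel, surfaces: list[str]):
    """Character bi-LSTM final states for each surface; with caches."""
    ids, mask, lengths = _char_batch(model, surfaces)
    emb = model.char_embed[ids]  # (N, maxlen, d_c)
    h_f, cache_f = model.char_fwd.forward(emb, mask)
    emb_r = reverse_padded(emb, lengths)
    h_b, cache_b = model.char_bwd.forward(emb_r, mask)
    rep = np.concatenate([h_f[:, -1], h_b[:, -1]], axis=1)  # (N, 2*h_c)
    caches = {
        "ids": ids, "mask": mask, "lengths": lengths,
        "cache_f": cache_f, "cache_b": cache_b, "shape": emb.shape,
    }
    return rep, caches


def _backprop_chars(
    model: TaggerModel, d_rep: np.ndarray, caches: dict
) -> dict[str, np.ndarray]:
    h_c = model.config.char_hidden_units
    N, maxlen, _ = caches["shape"]
    dh_f = np.zeros((N, maxlen, h_c))
    dh_f[:, -1] = d_rep[:, :h_c]
    dh_b = np.zeros((N, maxlen, h_c))
    dh_b[:, -1] = d_rep[:, h_c:]
    dx_f, g_f = model.char_fwd.backward(dh_f, caches["cache_f"])
    dx_b_rev, g_b = model.char_bwd.backward(dh_b, caches["cache_b"])
    dx = dx_f + reverse_padded(dx_b_rev, caches["lengths"])
    d_embed = np.zeros_like(model.char_embed)
    valid = caches["mask"].astype(bool)
    np.add.at(d_embed, caches["ids"][valid], dx[valid])
    d_embed[PAD_CHAR] = 0.0
    grads = {"char_embed": d_embed}
    grads.update({f"char_fwd.{k}": v for k, v in g_f.items()})
    grads.update({f"char_bwd.{k}": v for k, v in g_b.items()})
    return grads


def encode_characters(
    model: TaggerModel, sentence: AnnotatedSentence | Sequence[str]
) -> np.ndarray:
    """Per-token character representations for one sentence.

    Each row is the concatenation of the final forward and final
    backward states of the character bi-LSTM over that token's surface;
    shape (T, 2 * char_hidden_units).  Unknown characters map to a
    reserved unknown-character embedding.
    """
    surfaces = (
        sentence.surfaces
        if isinstance(sentence, AnnotatedSentence)
        else list(sentence)
    )
    if not surfaces:
        raise ValueError("sentence must be non-empty")
    rep, _ = _encode_chars_batch(model, surfaces)
    return rep


def build_token_input(
    char_repr: np.ndarray, word_level_vector: np.ndarray
) -> np.ndarray:
    """Concatenate the character representation with the word-level
    input vector (which is the zero vector for OOV units)."""
    return np.concatenate(
        [np.asarray(char_repr, float), np.asarray(word_level_vector, float)],
        axis=-1,
    )


def _word_vectors(
    descriptor: InputDescriptor, sentence: AnnotatedSentence
) -> np.ndarray:
    return np.stack(
        [descriptor.vector(t.surface, t.lemma) for t in sentence.tokens]
    )


def _batch_forward(
    model: TaggerModel,
    sentences: list[AnnotatedSentence],
    word_vecs: list[np.ndarray],
    dropout_rng: np.random.Generator | None,
):
    """Forward pass for a batch; returns emissions and a cache."""
    cfg = model.config
    B = len(sentences)
    lengths = np.array([len(s) for s in sentences], dtype=np.int64)
    T = int(lengths.max())
    d_in = 2 * cfg.char_hidden_units + model.descriptor.dimension

    surfaces = [t.surface for s in sentences for t in s.tokens]
    rep, char_caches = _encode_chars_batch(model, surfaces)

    X = np.zeros((B, T, d_in))
    mask = np.zeros((B, T))
    pos = 0
    for b, sent in enumerate(sentences):
        n = len(sent)
        X[b, :n, : 2 * cfg.char_hidden_units] = rep[pos : pos + n]
        X[b, :n, 2 * cfg.char_hidden_units :] = word_vecs[b]
        mask[b, :n] = 1.0
        pos += n

    drop_mask = None
    if dropout_rng is not None and cfg.dropout_rate > 0:
        keep = 1.0 - cfg.dropout_rate
        drop_mask = (
            dropout_rng.random(X.shape) < keep
        ).astype(float) / keep
        X = X * drop_mask

    h_f, cache_f = model.word_fwd.forward(X, mask)
    X_r = reverse_padded(X, lengths)
    h_b_rev, cache_b = model.word_bwd.forward(X_r, mask)
    h_b = reverse_padded(h_b_rev, lengths)
    H = np.concatenate([h_f, h_b], axis=2)  # (B, T, 2*h_w)
    emissions = H @ model.proj_W + model.proj_b
    cache = {
        "lengths": lengths, "mask": mask, "H": H,
        "cache_f": cache_f, "cache_b": cache_b,
        "char_caches": char_caches, "drop_mask": drop_mask,
        "n_tokens_per_sent": [len(s) for s in sentences],
    }
    return emissions, cache


def _batch_backward(
    model: TaggerModel, d_emissions: np.ndarray, cache: dict
) -> dict[str, np.ndarray]:
    cfg = model.config
    lengths = cache["lengths"]
    H = cache["H"]
    h_w = cfg.lstm_hidden_units

    B, T, L = d_emissions.shape
    d_proj_W = np.einsum("btk,btl->kl", H, d_emissions)
    d_proj_b = d_emissions.sum(axis=(0, 1))
    dH = d_emissions @ model.proj_W.T

    dx_f, g_f = model.word_fwd.backward(dH[:, :, :h_w], cache["cache_f"])
    dh_b = reverse_padded(dH[:, :, h_w:], lengths)
    dx_b_rev, g_b = model.word_bwd.backward(dh_b, cache["cache_b"])
    dX = dx_f + reverse_padded(dx_b_rev, lengths)

    if cache["drop_mask"] is not None:
        dX = dX * cache["drop_mask"]

    # gather gradients on the character representations
    d_rep = np.zeros(
        (sum(cache["n_tokens_per_sent"]), 2 * cfg.char_hidden_units)
    )
    pos = 0
    for b, n in enumerate(cache["n_tokens_per_sent"]):
        d_rep[pos : pos + n] = dX[b, :n, : 2 * cfg.char_hidden_units]
        pos += n
    grads = _backprop_chars(model, d_rep, cache["char_caches"])
    grads.update({f"word_fwd.{k}": v for k, v in g_f.items()})
    grads.update({f"word_bwd.{k}": v for k, v in g_b.items()})
    grads.update({"proj.W": d_proj_W, "proj.b": d_proj_b})
    return grads


def batch_loss_and_grads(
    model: TaggerModel,
    sentences: list[AnnotatedSentence],
    word_vecs: list[np.ndarray],
    gold_tag_ids: list[list[int]],
    dropout_rng: np.random.Generator | None = None,
):
    """Mean negative CRF log-likelihood of a batch and its gradients."""
    from .crf import crf_sequence_score

    emissions, cache = _batch_forward(model, sentences, word_vecs, dropout_rng)
    B = len(sentences)
    L = len(model.labels)
    d_emissions = np.zeros_like(emissions)
    d_trans = np.zeros((L, L))
    d_start = np.zeros(L)
    d_stop = np.zeros(L)
    loss = 0.0
    for b, sent in enumerate(sentences):
        n = len(sent)
        em = emissions[b, :n]
        tags = gold_tag_ids[b]
        unary, pairwise, startm, stopm, log_z = crf_marginals(em, model.crf)
        gold_score = crf_sequence_score(em, model.crf, tags)
        loss += (log_z - gold_score) / B
        d_em = unary.copy()
        d_em[np.arange(n), tags] -= 1.0
        d_emissions[b, :n] = d_em / B
        dt = pairwise.sum(axis=0)
        for a, c in zip(tags, tags[1:]):
            dt[a, c] -= 1.0
        d_trans += dt / B
        ds = startm.copy()
        ds[tags[0]] -= 1.0
        d_start += ds / B
        de = stopm.copy()
        de[tags[-1]] -= 1.0
        d_stop += de / B
    grads = _batch_backward(model, d_emissions, cache)
    grads.update(
        {"crf.trans": d_trans, "crf.start": d_start, "crf.stop": d_stop}
    )
    return loss, grads


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def predict(
    model: TaggerModel, corpus: AnnotatedCorpus
) -> list[list[str]]:
    """Viterbi-decode BIO tags for every sentence (dropout disabled)."""
    out: list[list[str]] = []
    for start in range(0, len(corpus.sentences), 64):
        chunk = corpus.sentences[start : start + 64]
        word_vecs = [_word_vectors(model.descriptor, s) for s in chunk]
        emissions, cache = _batch_forward(model, chunk, word_vecs, None)
        for b, sent in enumerate(chunk):
            n = len(sent)
            path, _ = viterbi_decode(emissions[b, :n], model.crf)
            out.append([model.labels[i] for i in path])
    return out


def _dev_f1(model: TaggerModel, corpus: AnnotatedCorpus) -> float:
    return score(corpus, predict(model, corpus), EXACT).micro["f1"]


def _snapshot(model: TaggerModel) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in model.parameters().items()}


def _restore(model: TaggerModel, snap: dict[str, np.ndarray]) -> None:
    for k, v in model.parameters().items():
        v[...] = snap[k]


def train(
    config: TaggerConfig,
    split: DataSplit,
    descriptor: InputDescriptor,
    evaluate_test: bool = True,
) -> tuple[TaggerModel, TrainReport]:
    """Train the tagger with early stopping on dev exact-match micro F1.

    Stops when the dev score has not improved for ``config.patience``
    consecutive epochs (or at ``max_epochs``) and returns the model
    restored to its best dev epoch.
    """
    if not split.train.sentences or not split.dev.sentences:
        raise ValueError("train and dev parts must be non-empty")
    if (
        config.word_vector_dim is not None
        and config.word_vector_dim != descriptor.dimension
    ):
        raise ValueError(
            f"config.word_vector_dim={config.word_vector_dim} does not match "
            f"descriptor dimension {descriptor.dimension}"
        )
    config = dataclasses.replace(config, word_vector_dim=descriptor.dimension)

    rng = np.random.default_rng(config.seed)
    labels = label_set(split.entity_inventory)
    label_index = {t: i for i, t in enumerate(labels)}
    char_vocab = build_char_vocab(split.train)
    model = TaggerModel.create(config, labels, char_vocab, descriptor, rng)

    train_sents = list(split.train.sentences)
    word_vecs = [_word_vectors(descriptor, s) for s in train_sents]
    gold_ids = [
        [label_index[t] for t in spans_to_bio(s)] for s in train_sents
    ]
    # bucket by length: sort once, batch contiguously, shuffle batch order
    order = sorted(range(len(train_sents)), key=lambda i: len(train_sents[i]))
    batches = [
        order[i : i + config.batch_size]
        for i in range(0, len(order), config.batch_size)
    ]

    optimiser = Adam(model.parameters(), lr=config.learning_rate)
    trace: list[float] = []
    best_f1 = -1.0
    best_epoch = 0
    best_snap = _snapshot(model)
    epochs_without_improvement = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        for bi in rng.permutation(len(batches)):
            idx = batches[bi]
            loss, grads = batch_loss_and_grads(
                model,
                [train_sents[i] for i in idx],
                [word_vecs[i] for i in idx],
                [gold_ids[i] for i in idx],
                dropout_rng=rng,
            )
            clip_global_norm(grads, config.clip_norm)
            optimiser.step(grads)
        f1 = _dev_f1(model, split.dev)
        trace.append(f1)
        if f1 > best_f1:
            epochs_without_improvement = 0
            best_f1 = f1
            best_epoch = epoch
            best_snap = _snapshot(model)
        else:
            if f1 == best_f1:
                # a tie keeps the latest epoch's parameters — equally
                # good on dev, better fitted to the training data — but
                # still counts as "no improvement" for the stopping rule
                best_epoch = epoch
                best_snap = _snapshot(model)
            epochs_without_improvement += 1
            if (
                epochs_without_improvement >= config.patience
                and epoch >= config.min_epochs
            ):
                break
    _restore(model, best_snap)
    test_metrics = None
    if evaluate_test and split.test.sentences:
        test_metrics = score(split.test, predict(model, split.test), EXACT)
    return model, TrainReport(trace, best_epoch, epoch, test_metrics)


def grid_search(
    grid: Sequence[TaggerConfig],
    split: DataSplit,
    descriptor: InputDescriptor,
):
    """Exhaustive grid search scored by best dev exact-match micro F1.

    Returns (best_config, table); ties break toward the earlier grid
    entry.  The table records each config's dev score.
    """
    import pandas as pd

    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best_i, best_f1 = 0, -1.0
    for i, cfg in enumerate(grid):
        _, report = train(cfg, split, descriptor, evaluate_test=False)
        f1 = report.best_dev_f1
        row = asdict(cfg)
        row["dev_f1"] = f1
        rows.append(row)
        if f1 > best_f1:
            best_i, best_f1 = i, f1
    return grid[best_i], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: TaggerModel, directory: str | Path) -> None:
    """Persist parameters, label set, character vocabulary, config and
    the input descriptor's embedding spaces to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **model.parameters())
    meta = {
        "labels": model.labels,
        "char_vocab": model.char_vocab,
        "config": asdict(model.config),
        "feature": model.descriptor.feature,
        "has_word_space": model.descriptor.word_space is not None,
        "has_lemma_space": model.descriptor.lemma_space is not None,
    }
    (directory / "meta.json").write_text(json.dumps(meta), encoding="utf-8")
    if model.descriptor.word_space is not None:
        write_word2vec(model.descriptor.word_space, directory / "word.vec")
    if model.descriptor.lemma_space is not None:
        write_word2vec(model.descriptor.lemma_space, directory / "lemma.vec")


def load_model(directory: str | Path) -> TaggerModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    word_space = (
        read_word2vec(directory / "word.vec") if meta["has_word_space"] else None
    )
    lemma_space = (
        read_word2vec(directory / "lemma.vec")
        if meta["has_lemma_space"]
        else None
    )
    descriptor = InputDescriptor(meta["feature"], word_space, lemma_space)
    config = TaggerConfig(**meta["config"])
    model = TaggerModel.create(
        config,
        meta["labels"],
        meta["char_vocab"],
        descriptor,
        np.random.default_rng(config.seed),
    )
    arrays = np.load(directory / "params.npz")
    for k, v in model.parameters().items():
        v[...] = arrays[k]
    return model
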