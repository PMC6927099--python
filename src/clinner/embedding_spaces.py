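"""Word and lemma embedding spaces and their combination algebra.

Two embedding spaces are used throughout: one over surface word-forms
(W, vocabulary Σ_W, dimension n) and one over lemmas (L, vocabulary
Σ_L, dimension m).  Lookup is total: a unit outside the vocabulary maps
to the all-zero vector of the space's dimension.  The spaces are
combined per token by one of three operators

* concatenate  (W,L):  (e_w(w), e_l(l))            ∈ R^{n+m}
* sum          (W+L):  e_w(w) + e_l(l)             ∈ R^n   (requires n = m)
* subtract     (W−L):  e_w(w) − e_l(l)             ∈ R^n   (requires n = m)

and the resulting vector is the word-level input to the sequence tagger.

Training is distributional: skip-gram with negative sampling
("word2vec"), a co-occurrence weighted-least-squares factorisation
("glove"), or skip-gram with bag-of-character-n-gram composition
("fasttext").  All three return the same :class:`EmbeddingSpace`
container and are interchangeable downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingSpace",
    "CombinationMode",
    "InputDescriptor",
    "train_space",
    "lookup",
    "combine",
    "cosine_similarity",
    "nearest_neighbours",
    "pca_project_2d",
    "read_word2vec",
    "write_word2vec",
    "display_similarity",
]


@dataclass
class EmbeddingSpace:
    """A vocabulary → fixed-dimension vector mapping.

    Vectors are stored row-wise in a single matrix; ``index`` maps each
    vocabulary item to its row.
    """

    dimension: int
    index: dict[str, int]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.dimension:
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"dimension {self.dimension}"
            )
        if len(self.index) != self.matrix.shape[0]:
            raise ValueError("index size does not match matrix rows")

    @classmethod
    def from_mapping(cls, vectors: Mapping[str, Sequence[float]]) -> "EmbeddingSpace":
        items = list(vectors.items())
        if not items:
            raise ValueError("cannot build an empty embedding space")
        dim = len(items[0][1])
        index = {tok: i for i, (tok, _) in enumerate(items)}
        matrix = np.array([v for _, v in items], dtype=np.float64)
        return cls(dim, index, matrix)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.index)

    def __contains__(self, unit: str) -> bool:
        return unit in self.index

    def __len__(self) -> int:
        return len(self.index)


class CombinationMode(str, Enum):
    CONCATENATE = "concatenate"
    SUM = "sum"
    SUBTRACT = "subtract"


def lookup(space: EmbeddingSpace, unit: str) -> np.ndarray:
    """Total lookup: stored vector, or the zero vector for OOV units."""
    i = space.index.get(unit)
    if i is None:
        return np.zeros(space.dimension)
    return space.matrix[i].copy()


def combine(
    word_space: EmbeddingSpace,
    lemma_space: EmbeddingSpace,
    w: str,
    l: str,
    mode: CombinationMode | str,
) -> np.ndarray:
    """Combine the word-form and lemma embeddings of one token."""
    mode = CombinationMode(mode)
    ew = lookup(word_space, w)
    el = lookup(lemma_space, l)
    if mode is CombinationMode.CONCATENATE:
        return np.concatenate([ew, el])
    if word_space.dimension != lemma_space.dimension:
        raise ValueError(
            f"{mode.value} requires equal dimensions, got "
            f"{word_space.dimension} and {lemma_space.dimension}"
        )
    return ew + el if mode is CombinationMode.SUM else ew - el


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between u and v, in [-1, 1].

    Either argument may be the zero vector (the OOV rule makes this
    reachable); the similarity is then defined as 0 with a warning.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn(
            "cosine similarity with a zero vector is undefined; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def display_similarity(value: float) -> float:
    """Round half-up to two decimals (display precision for reports)."""
    return math.floor(value * 100 + 0.5) / 100 if value >= 0 else -math.floor(-value * 100 + 0.5) / 100


def nearest_neighbours(
    space: EmbeddingSpace, term: str, k: int
) -> list[tuple[str, float]]:
    """Top-k vocabulary items by cosine similarity to ``term``.

    The query itself is excluded; ties are broken lexicographically.
    An OOV query yields an empty list with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if term not in space:
        warnings.warn(
            f"term {term!r} not in vocabulary; no neighbours",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    q = space.matrix[space.index[term]]
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(space.matrix, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = space.matrix @ q / (norms * qn)
    sims = np.nan_to_num(sims, nan=0.0)
    scored = [
        (tok, float(sims[i])) for tok, i in space.index.items() if tok != term
    ]
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored[:k]


def pca_project_2d(
    space: EmbeddingSpace, terms: Sequence[str]
) -> dict[str, np.ndarray]:
    """Project selected terms onto their top-2 principal components."""
    from sklearn.decomposition import PCA

    usable = [t for t in terms if t in space and np.any(space.matrix[space.index[t]])]
    if len(usable) < 2:
        raise ValueError("need at least 2 in-vocabulary non-zero terms")
    X = np.stack([space.matrix[space.index[t]] for t in usable])
    coords = PCA(n_components=2).fit_transform(X)
    return {t: coords[i] for i, t in enumerate(usable)}


# ---------------------------------------------------------------------------
# input feature descriptors
# ---------------------------------------------------------------------------

_FEATURES = ("W", "L", "WL", "WplusL", "WminusL")
_FEATURE_MODE = {
    "WL": CombinationMode.CONCATENATE,
    "WplusL": CombinationMode.SUM,
    "WminusL": CombinationMode.SUBTRACT,
}


@dataclass
class InputDescriptor:
    """Names which embedding feature feeds the tagger.

    ``feature`` is one of W, L, WL (concatenation), WplusL (sum),
    WminusL (difference) — the run-time switch between word-only,
    lemma-only, and combined inputs.
    """

    feature: str
    word_space: EmbeddingSpace | None = None
    lemma_space: EmbeddingSpace | None = None

    def __post_init__(self) -> None:
        if self.feature not in _FEATURES:
            raise ValueError(
                f"feature must be one of {_FEATURES}, got {self.feature!r}"
            )
        if self.feature != "L" and self.word_space is None:
            raise ValueError(f"feature {self.feature} requires a word space")
        if self.feature != "W" and self.lemma_space is None:
            raise ValueError(f"feature {self.feature} requires a lemma space")
        if self.feature in ("WplusL", "WminusL"):
            if self.word_space.dimension != self.lemma_space.dimension:
                raise ValueError(
                    "sum/subtract features require equal space dimensions"
                )

    @property
    def dimension(self) -> int:
        if self.feature == "W":
            return self.word_space.dimension
        if self.feature == "L":
            return self.lemma_space.dimension
        if self.feature == "WL":
            return self.word_space.dimension + self.lemma_space.dimension
        return self.word_space.dimension

    def vector(self, surface: str, lemma: str) -> np.ndarray:
        if self.feature == "W":
            return lookup(self.word_space, surface)
        if self.feature == "L":
            return lookup(self.lemma_space, lemma)
        return combine(
            self.word_space, self.lemma_space, surface, lemma,
            _FEATURE_MODE[self.feature],
        )


# ---------------------------------------------------------------------------
# word2vec text format I/O
# ---------------------------------------------------------------------------

def write_word2vec(space: EmbeddingSpace, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    lines = []
    if header:
        lines.append(f"{len(space)} {space.dimension}")
    for tok, i in space.index.items():
        vals = " ".join(repr(float(x)) for x in space.matrix[i])
        lines.append(f"{tok} {vals}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_word2vec(path: str | Path) -> EmbeddingSpace:
    """Read word2vec text format (optional ``<count> <dim>`` header)."""
    path = Path(path)
    index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.split()
        has_header = len(parts) == 2 and all(p.isdigit() for p in parts)
        if not has_header and parts:
            index[parts[0]] = 0
            rows.append(np.array([float(x) for x in parts[1:]]))
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            index[parts[0]] = len(rows)
            rows.append(np.array([float(x) for x in parts[1:]]))
    if not rows:
        raise ValueError(f"{path}: no vectors found")
    dims = {len(r) for r in rows}
    if len(dims) != 1:
        raise ValueError(f"{path}: inconsistent vector dimensions {sorted(dims)}")
    return EmbeddingSpace(dims.pop(), index, np.stack(rows))


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def _build_vocab(
    sentences: Sequence[Sequence[str]], min_count: int
) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {
        tok: i
        for i, (tok, c) in enumerate(sorted(counts.items()))
        if c >= min_count
    }
    vocab = {tok: i for i, tok in enumerate(vocab)}  # re-densify indices
    freqs = np.array([counts[tok] for tok in vocab], dtype=np.float64)
    return vocab, freqs


def _skipgram_pairs(
    sentences: Sequence[Sequence[str]],
    vocab: Mapping[str, int],
    window: int,
) -> np.ndarray:
    pairs: list[tuple[int, int]] = []
    for sent in sentences:
        ids = [vocab[t] for t in sent if t in vocab]
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            hi = min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((c, ids[j]))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))




def _train_sgns(
    sentences: Sequence[Sequence[str]],
    dimension: int,
    window: int,
    min_count: int,
    epochs: int,
    negatives: int,
    lr: float,
    rng: np.random.Generator,
    subwords: bool = False,
) -> EmbeddingSpace:
    """Skip-gram with negative sampling, mini-batched in numpy.

    With ``subwords=True`` the centre-word representation is the sum of
    the word vector and its character 3-5-gram vectors (bag-of-subwords
    composition); exported vectors are the composed ones.
    """
    vocab, freqs = _build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min-count filtering")
    V = len(vocab)
    pairs = _skipgram_pairs(sentences, vocab, window)
    if len(pairs) == 0:
        raise ValueError("corpus yields no skip-gram pairs")

    # subword inventory (fasttext-style character n-grams of the padded form)
    ngram_ids: list[list[int]] = [[] for _ in range(V)]
    n_ngrams = 0
    if subwords:
        ngram_index: dict[str, int] = {}
        for tok, i in vocab.items():
            padded = f"<{tok}>"
            for n in (3, 4, 5):
                for s in range(len(padded) - n + 1):
                    g = padded[s : s + n]
                    gid = ngram_index.setdefault(g, len(ngram_index))
                    ngram_ids[i].append(gid)
        n_ngrams = len(ngram_index)

    bound = 0.5 / dimension
    W_in = rng.uniform(-bound, bound, size=(V, dimension))
    W_out = np.zeros((V, dimension))
    G_in = (
        rng.uniform(-bound, bound, size=(n_ngrams, dimension))
        if subwords
        else None
    )

    noise = freqs ** 0.75
    noise /= noise.sum()
    # small batches keep the vectorised update close to the sequential
    # stochastic update even on small-vocabulary corpora
    batch = 128
    n_pairs = len(pairs)
    total_steps = max(1, epochs * ((n_pairs + batch - 1) // batch))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            idx = pairs[order[start : start + batch]]
            centers, contexts = idx[:, 0], idx[:, 1]
            B = len(centers)
            alpha = lr * max(1e-4, 1.0 - step / total_steps)
            step += 1

            vc = W_in[centers]
            if subwords:
                vc = vc.copy()
                for r, c in enumerate(centers):
                    gids = ngram_ids[c]
                    if gids:
                        vc[r] += G_in[gids].sum(axis=0)
            neg = rng.choice(V, size=(B, negatives), p=noise)
            # positive and negative scores
            pos = _sigmoid(np.einsum("bd,bd->b", vc, W_out[contexts]))
            negs = _sigmoid(np.einsum("bd,bkd->bk", vc, W_out[neg]))

            g_pos = (pos - 1.0)[:, None]  # d loss / d (vc . u_pos)
            g_neg = negs[:, :, None]

            grad_vc = g_pos * W_out[contexts] + np.einsum(
                "bkd,bk->bd", W_out[neg], negs
            )
            grad_ctx = g_pos * vc
            grad_negv = g_neg * vc[:, None, :]

            np.add.at(W_out, contexts, -alpha * grad_ctx)
            np.add.at(
                W_out, neg.ravel(), -alpha * grad_negv.reshape(-1, dimension)
            )
            np.add.at(W_in, centers, -alpha * grad_vc)
            if subwords:
                for r, c in enumerate(centers):
                    gids = ngram_ids[c]
                    if gids:
                        G_in[gids] -= alpha * grad_vc[r]

    matrix = W_in
    if subwords:
        matrix = W_in.copy()
        for tok, i in vocab.items():
            gids = ngram_ids[i]
            if gids:
                matrix[i] += G_in[gids].sum(axis=0)
    return EmbeddingSpace(dimension, dict(vocab), matrix)


def _train_glove(
    sentences: Sequence[Sequence[str]],
    dimension: int,
    window: int,
    min_count: int,
    epochs: int,
    lr: float,
    rng: np.random.Generator,
) -> EmbeddingSpace:
    """Weighted least-squares factorisation of log co-occurrence counts
    with the f(x) = min(1, (x/x_max)^0.75 ) weighting, fit by Adagrad.
    """
    vocab, _ = _build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min-count filtering")
    V = len(vocab)
    cooc: dict[tuple[int, int], float] = {}
    for sent in sentences:
        ids = [vocab[t] for t in sent if t in vocab]
        for i, c in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j == i:
                    continue
                cooc[(c, ids[j])] = cooc.get((c, ids[j]), 0.0) + 1.0 / abs(j - i)
    if not cooc:
        raise ValueError("corpus yields no co-occurrences")
    keys = np.array(list(cooc.keys()), dtype=np.int64)
    xs = np.array(list(cooc.values()))
    logx = np.log(xs)
    wts = np.minimum(1.0, (xs / 100.0) ** 0.75)

    bound = 0.5 / dimension
    Wm = rng.uniform(-bound, bound, size=(V, dimension))
    Cm = rng.uniform(-bound, bound, size=(V, dimension))
    bw = np.zeros(V)
    bc = np.zeros(V)
    gW = np.ones_like(Wm)
    gC = np.ones_like(Cm)
    gbw = np.ones(V)
    gbc = np.ones(V)

    n = len(keys)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, 4096):
            sel = order[start : start + 4096]
            wi, ci = keys[sel, 0], keys[sel, 1]
            diff = (
                np.einsum("bd,bd->b", Wm[wi], Cm[ci])
                + bw[wi]
                + bc[ci]
                - logx[sel]
            )
            f = wts[sel] * diff
            gw = f[:, None] * Cm[ci]
            gc = f[:, None] * Wm[wi]
            np.add.at(gW, wi, gw ** 2)
            np.add.at(gC, ci, gc ** 2)
            np.add.at(Wm, wi, -lr * gw / np.sqrt(gW[wi]))
            np.add.at(Cm, ci, -lr * gc / np.sqrt(gC[ci]))
            np.add.at(gbw, wi, f ** 2)
            np.add.at(gbc, ci, f ** 2)
            np.add.at(bw, wi, -lr * f / np.sqrt(gbw[wi]))
            np.add.at(bc, ci, -lr * f / np.sqrt(gbc[ci]))
    return EmbeddingSpace(dimension, dict(vocab), Wm + Cm)


def train_space(
    sentences: Sequence[Sequence[str]] | Iterable[str],
    algorithm: str = "word2vec",
    dimension: int = 300,
    window: int = 5,
    min_count: int = 1,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingSpace:
    """Train an embedding space on a raw tokenised corpus.

    ``sentences`` is a sequence of token sequences (strings are split on
    whitespace).  ``algorithm`` is one of ``word2vec`` (skip-gram with
    negative sampling), ``glove`` (co-occurrence factorisation) or
    ``fasttext`` (skip-gram with character n-gram composition).
    Defaults: dimension 300, window 5, min_count 1.
    """
    sents = [
        s.split() if isinstance(s, str) else list(s) for s in sentences
    ]
    sents = [s for s in sents if s]
    if not sents:
        raise ValueError("cannot train embeddings on an empty corpus")
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(seed)
    if algorithm in ("word2vec", "skipgram"):
        return _train_sgns(
            sents, dimension, window, min_count, epochs, 5, 0.025, rng
        )
    if algorithm == "fasttext":
        return _train_sgns(
            sents, dimension, window, min_count, epochs, 5, 0.025, rng,
            subwords=True,
        )
    if algorithm == "glove":
        return _train_glove(sents, dimension, window, min_count, epochs, 0.05, rng)
    raise ValueError(f"unknown algorithm {algorithm!r}")
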