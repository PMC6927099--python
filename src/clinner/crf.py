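"""Linear-chain conditional random field over BIO tag sequences.

A tag sequence y for a sentence of length T is scored as

    s(y) = start[y_1] + Σ_t emissions[t, y_t]
         + Σ_t transitions[y_{t-1}, y_t] + stop[y_T]

The log-partition (normaliser over all |L|^T sequences) is computed by
the forward recursion in log space; decoding is Viterbi with ties broken
toward the lower label index; gradients of the log-likelihood use the
forward-backward marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CRFParams",
    "crf_sequence_score",
    "crf_log_partition",
    "viterbi_decode",
    "crf_marginals",
]


@dataclass
class CRFParams:
    """Transition scores: square matrix over labels plus start/stop."""

    transitions: np.ndarray  # (L, L): transitions[i, j] = score of i -> j
    start: np.ndarray  # (L,)
    stop: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        self.stop = np.asarray(self.stop, dtype=np.float64)
        L = self.transitions.shape[0]
        if self.transitions.shape != (L, L):
            raise ValueError("transition matrix must be square")
        if self.start.shape != (L,) or self.stop.shape != (L,):
            raise ValueError("start/stop shapes must match label count")

    @property
    def n_labels(self) -> int:
        return self.transitions.shape[0]

    @classmethod
    def zeros(cls, n_labels: int) -> "CRFParams":
        return cls(
            np.zeros((n_labels, n_labels)),
            np.zeros(n_labels),
            np.zeros(n_labels),
        )


def _check(emissions: np.ndarray, params: CRFParams) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[1] != params.n_labels:
        raise ValueError(
            f"emissions shape {emissions.shape} incompatible with "
            f"{params.n_labels} labels"
        )
    if emissions.shape[0] == 0:
        raise ValueError("empty sequence")
    return emissions


def crf_sequence_score(
    emissions: np.ndarray, params: CRFParams, tags: Sequence[int]
) -> float:
    """Unnormalised score of one tag sequence."""
    emissions = _check(emissions, params)
    tags = list(tags)
    if len(tags) != emissions.shape[0]:
        raise ValueError(
            f"{len(tags)} tags for {emissions.shape[0]} emission rows"
        )
    score = params.start[tags[0]] + params.stop[tags[-1]]
    score += emissions[np.arange(len(tags)), tags].sum()
    for a, b in zip(tags, tags[1:]):
        score += params.transitions[a, b]
    return float(score)


def crf_log_partition(emissions: np.ndarray, params: CRFParams) -> float:
    """log Σ_y exp(score(y)) over all tag sequences, forward recursion."""
    emissions = _check(emissions, params)
    alpha = params.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        # alpha[j] = logsumexp_i(alpha[i] + trans[i, j]) + emit[t, j]
        alpha = logsumexp(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha + params.stop))


def viterbi_decode(
    emissions: np.ndarray, params: CRFParams
) -> tuple[list[int], float]:
    """Highest-scoring tag sequence and its score.

    Ties are broken toward the lower label index at every backtrack
    step (argmax takes the first maximiser).
    """
    emissions = _check(emissions, params)
    T, L = emissions.shape
    delta = params.start + emissions[0]
    back = np.zeros((T, L), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + params.transitions  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + emissions[t]
    delta = delta + params.stop
    best_last = int(np.argmax(delta))
    best_score = float(delta[best_last])
    path = [best_last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best_score


def crf_marginals(
    emissions: np.ndarray, params: CRFParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Forward-backward marginals under the CRF distribution.

    Returns ``(unary, pairwise, start_marg, stop_marg, log_z)`` where
    ``unary[t, j] = P(y_t = j)``, ``pairwise[t, i, j] = P(y_t = i,
    y_{t+1} = j)`` for t in [0, T-2], ``start_marg = unary[0]`` and
    ``stop_marg = unary[T-1]``.
    """
    emissions = _check(emissions, params)
    T, L = emissions.shape
    alpha = np.empty((T, L))
    beta = np.empty((T, L))
    alpha[0] = params.start + emissions[0]
    for t in range(1, T):
        alpha[t] = (
            logsumexp(alpha[t - 1][:, None] + params.transitions, axis=0)
            + emissions[t]
        )
    beta[T - 1] = params.stop
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(
            params.transitions + (emissions[t + 1] + beta[t + 1])[None, :],
            axis=1,
        )
    log_z = float(logsumexp(alpha[T - 1] + params.stop))
    unary = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((max(T - 1, 0), L, L))
    for t in range(T - 1):
        log_pair = (
            alpha[t][:, None]
            + params.transitions
            + (emissions[t + 1] + beta[t + 1])[None, :]
            - log_z
        )
        pairwise[t] = np.exp(log_pair)
    return unary, pairwise, unary[0], unary[-1], log_z
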