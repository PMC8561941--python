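"""Skip-gram with negative sampling for walk corpora.

A compact, fully seeded word2vec-style trainer: input/output embedding
matrices, unigram^(3/4) noise distribution, per-position reduced window, and
a linearly decaying learning rate.  Pair and negative-sample streams are
pregenerated with a seeded numpy generator; the stochastic-gradient inner
loop is a sequential, single-threaded numba kernel, so a given corpus, seed
and configuration always produce bit-identical vectors (the single-worker
determinism the evaluation protocol relies on).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .exceptions import ContractError

_MIN_ALPHA = 1e-4
_CLIP = 15.0


def _build_vocab(corpus: Sequence[Sequence[str]]) -> tuple[dict[str, int], np.ndarray]:
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for sentence in corpus:
        for tok in sentence:
            i = vocab.setdefault(tok, len(vocab))
            if i == len(counts):
                counts.append(0)
            counts[i] += 1
    return vocab, np.array(counts, dtype=float)


def _pair_arrays(
    encoded: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) pairs for one epoch, with reduced windows, shuffled."""
    tokens = np.concatenate(encoded)
    sent_id = np.concatenate(
        [np.full(len(s), i, dtype=np.int64) for i, s in enumerate(encoded)]
    )
    b = rng.integers(1, window + 1, size=len(tokens))
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    pos = np.arange(len(tokens))
    for k in range(1, window + 1):
        left, right = pos[:-k], pos[k:]
        same = sent_id[left] == sent_id[right]
        fwd = same & (b[left] >= k)  # center i, context i+k
        bwd = same & (b[right] >= k)  # center i+k, context i
        centers.append(tokens[left[fwd]])
        contexts.append(tokens[right[fwd]])
        centers.append(tokens[right[bwd]])
        contexts.append(tokens[left[bwd]])
    center_arr = np.concatenate(centers)
    context_arr = np.concatenate(contexts)
    # decorrelate the SGD stream: generation order groups pairs by offset
    order = rng.permutation(center_arr.size)
    return center_arr[order], context_arr[order]


@njit(cache=True)
def _sgd_epoch(
    centers: np.ndarray,
    contexts: np.ndarray,
    negatives: np.ndarray,
    w_in: np.ndarray,
    w_out: np.ndarray,
    lr_start: float,
    lr_end: float,
) -> None:  # pragma: no cover - exercised through train_skipgram
    n_pairs = centers.shape[0]
    n_neg = negatives.shape[1]
    dim = w_in.shape[1]
    grad_v = np.empty(dim)
    for i in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * (i / n_pairs)
        c = centers[i]
        grad_v[:] = 0.0
        for j in range(1 + n_neg):
            if j == 0:
                t = contexts[i]
                label = 1.0
            else:
                t = negatives[i, j - 1]
                label = 0.0
            score = 0.0
            for dd in range(dim):
                score += w_in[c, dd] * w_out[t, dd]
            if score > _CLIP:
                score = _CLIP
            elif score < -_CLIP:
                score = -_CLIP
            g = (1.0 / (1.0 + np.exp(-score)) - label) * lr
            for dd in range(dim):
                grad_v[dd] += g * w_out[t, dd]
                w_out[t, dd] -= g * w_in[c, dd]
        for dd in range(dim):
            w_in[c, dd] -= grad_v[dd]


def train_skipgram(
    corpus: Sequence[Sequence[str]],
    dimensions: int,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
) -> Mapping[str, np.ndarray]:
    """Train embeddings on a corpus of token sequences.

    Returns a dict token -> input-embedding vector of length ``dimensions``.
    """
    corpus = [s for s in corpus if len(s) > 0]
    if not corpus:
        raise ContractError("empty corpus")
    if dimensions < 1 or window < 1 or epochs < 1 or negative < 0:
        raise ContractError("invalid skip-gram hyperparameters")
    vocab, counts = _build_vocab(corpus)
    n_vocab = len(vocab)
    encoded = [np.array([vocab[t] for t in s], dtype=np.int64) for s in corpus]
    rng = np.random.default_rng(seed)
    w_in = (rng.random((n_vocab, dimensions)) - 0.5) / dimensions
    w_out = np.zeros((n_vocab, dimensions))
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    for epoch in range(epochs):
        centers, contexts = _pair_arrays(encoded, window, rng)
        negatives = np.minimum(
            np.searchsorted(noise_cdf, rng.random((centers.size, max(negative, 1)))),
            n_vocab - 1,
        ).astype(np.int64)
        if negative == 0:
            negatives = negatives[:, :0]
        lr_start = max(alpha * (1 - epoch / epochs), _MIN_ALPHA)
        lr_end = max(alpha * (1 - (epoch + 1) / epochs), _MIN_ALPHA)
        _sgd_epoch(centers, contexts, negatives, w_in, w_out, lr_start, lr_end)
    return {tok: w_in[i].copy() for tok, i in vocab.items()}
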