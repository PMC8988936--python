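"""Skip-gram with negative sampling over walk and literature corpora.

Classic word2vec SGNS: for each center token, context tokens within a
dynamically reduced window are predicted against ``negatives`` samples drawn
from the unigram^0.75 noise distribution.  Training is a numba-compiled SGD
loop (single stream, seeded), so identical inputs give identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numba import njit

from .vectors import EmbeddingTable

_NOISE_POWER = 0.75
_NOISE_TABLE_SIZE = 1_000_000


@dataclass
class SkipGramConfig:
    """Hyperparameters; dimension/window/negatives default to 128/10/5."""

    dimension: int = 128
    window: int = 10
    negatives: int = 5
    min_count: int = 1
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    subsample: float = 1e-3  # frequent-word downsampling threshold; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.window < 1 or self.min_count < 1 or self.epochs < 1:
            raise ValueError("dimension, window, min_count and epochs must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")


def _build_vocab(sentences: list[list[str]], min_count: int) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sentence in sentences:
        for token in sentence:
            counts[token] = counts.get(token, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary after applying min_count")
    index = {t: i for i, t in enumerate(vocab)}
    freqs = np.array([counts[t] for t in vocab], dtype=np.float64)
    return vocab, index, freqs


def _noise_table(freqs: np.ndarray) -> np.ndarray:
    """Unigram^0.75 sampling table (word2vec style)."""
    p = freqs ** _NOISE_POWER
    p /= p.sum()
    bounds = np.cumsum(p) * _NOISE_TABLE_SIZE
    table = np.zeros(_NOISE_TABLE_SIZE, dtype=np.int32)
    word = 0
    for i in range(_NOISE_TABLE_SIZE):
        table[i] = word
        if i >= bounds[word] and word < len(p) - 1:
            word += 1
    return table


@njit(cache=True)
def _sgns_train(
    w_in,
    w_out,
    tokens,
    offsets,
    noise_table,
    keep_prob,
    window,
    negatives,
    epochs,
    alpha0,
    min_alpha,
    seed,
):
    """SGD over all (center, context) pairs; one seeded stream, in place."""
    np.random.seed(seed)
    dim = w_in.shape[1]
    n_sent = offsets.shape[0] - 1
    total_steps = epochs * n_sent
    step = 0
    grad = np.empty(dim)
    max_len = 0
    for s in range(n_sent):
        length = offsets[s + 1] - offsets[s]
        if length > max_len:
            max_len = length
    kept = np.empty(max_len, dtype=np.int32)
    for _epoch in range(epochs):
        for s in range(n_sent):
            alpha = alpha0 + (min_alpha - alpha0) * (step / max(total_steps - 1, 1))
            step += 1
            # frequent-word subsampling: drop tokens from the stream so that
            # rare tokens get wider effective contexts
            n_kept = 0
            for pos in range(offsets[s], offsets[s + 1]):
                if np.random.random() < keep_prob[tokens[pos]]:
                    kept[n_kept] = tokens[pos]
                    n_kept += 1
            start, stop = 0, n_kept
            for pos in range(start, stop):
                center = kept[pos]
                b = 1 + np.random.randint(window)  # reduced window
                lo = max(start, pos - b)
                hi = min(stop, pos + b + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = kept[cpos]
                    for d in range(dim):
                        grad[d] = 0.0
                    v = w_in[center]
                    # positive sample
                    dot = 0.0
                    for d in range(dim):
                        dot += v[d] * w_out[context, d]
                    g = (1.0 / (1.0 + np.exp(-dot)) - 1.0) * alpha
                    for d in range(dim):
                        grad[d] += g * w_out[context, d]
                        w_out[context, d] -= g * v[d]
                    # negative samples
                    for _k in range(negatives):
                        neg = noise_table[np.random.randint(noise_table.shape[0])]
                        if neg == context:
                            continue
                        dot = 0.0
                        for d in range(dim):
                            dot += v[d] * w_out[neg, d]
                        g = (1.0 / (1.0 + np.exp(-dot))) * alpha
                        for d in range(dim):
                            grad[d] += g * w_out[neg, d]
                            w_out[neg, d] -= g * v[d]
                    for d in range(dim):
                        w_in[center, d] -= grad[d]


def train_skipgram(corpus: Iterable[Iterable[str]], config: SkipGramConfig) -> EmbeddingTable:
    """Train SGNS embeddings over a corpus of token sentences.

    Accepts a :class:`~kglit.walks.WalkCorpus`, a
    :class:`~kglit.textnorm.TextCorpus`, or any iterable of token lists.
    Tokens below ``min_count`` are dropped from sentences before windowing.
    """
    sentences = [list(s) for s in corpus]
    if not any(sentences):
        raise ValueError("empty corpus")
    vocab, index, freqs = _build_vocab(sentences, config.min_count)

    encoded: list[int] = []
    offsets = [0]
    for sentence in sentences:
        ids = [index[t] for t in sentence if t in index]
        encoded.extend(ids)
        offsets.append(len(encoded))
    tokens = np.array(encoded, dtype=np.int32)
    offset_arr = np.array(offsets, dtype=np.int64)

    rng = np.random.Generator(np.random.PCG64(config.seed))
    dim = config.dimension
    w_in = ((rng.random((len(vocab), dim)) - 0.5) / dim).astype(np.float64)
    w_out = np.zeros((len(vocab), dim), dtype=np.float64)
    noise = _noise_table(freqs)
    # word2vec-style downsampling of frequent tokens
    if config.subsample > 0:
        rel = freqs / freqs.sum()
        keep_prob = np.minimum(
            1.0, np.sqrt(config.subsample / rel) + config.subsample / rel
        )
    else:
        keep_prob = np.ones(len(vocab))

    _sgns_train(
        w_in,
        w_out,
        tokens,
        offset_arr,
        noise,
        keep_prob,
        config.window,
        config.negatives,
        config.epochs,
        config.alpha,
        config.min_alpha,
        config.seed % (2**31),
    )
    # represent each token by the sum of its input and output vectors: the
    # input-input product captures second-order (shared-context) similarity,
    # the input-output cross terms first-order co-occurrence (~PMI), so the
    # sum reflects both.  Subtracting the vocabulary mean removes the common
    # anisotropy direction that negative sampling induces on small corpora,
    # leaving cosine similarity meaningful.
    vectors = w_in + w_out
    vectors -= vectors.mean(axis=0)
    return EmbeddingTable(vocab, vectors)
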