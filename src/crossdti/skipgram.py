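"""A small skip-gram-with-negative-sampling (SGNS) word embedder.

Trains dense vectors for sequence tokens (here: protein k-mers) by sliding a
context window over token sentences and optimising the standard SGNS
objective — the dot product of centre and context vectors is pushed up for
observed pairs and down for ``n_negative`` noise tokens drawn from the
unigram^0.75 distribution.  Single-threaded, seeded, plain NumPy: runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_sgns(
    sentences: list[list[str]],
    dim: int,
    window: int = 5,
    epochs: int = 5,
    n_negative: int = 5,
    learning_rate: float = 0.025,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train SGNS vectors; returns a token -> vector (length ``dim``) map.

    The learning rate decays linearly to 10% of its initial value over the
    training pass.  Vocabulary order is the sorted distinct-token set, so the
    parameterisation is independent of sentence order.
    """
    vocab = sorted({tok for sent in sentences for tok in sent})
    if not vocab:
        raise ValueError("empty corpus: no tokens to embed")
    index = {tok: i for i, tok in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    for sent in sentences:
        for tok in sent:
            counts[index[tok]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    v = len(vocab)
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    # Pre-compute (centre, context) pairs once; shuffle per epoch.
    pairs: list[tuple[int, int]] = []
    for sent in sentences:
        ids = [index[t] for t in sent]
        for i, ci in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((ci, ids[j]))
    if not pairs:
        # single-token sentences have no context; the seeded init still
        # provides a usable vector per vocabulary entry
        return {tok: w_in[index[tok]].copy() for tok in vocab}

    pair_arr = np.array(pairs, dtype=np.int64)
    total_steps = epochs * len(pair_arr)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        neg = rng.choice(v, size=(len(pair_arr), n_negative), p=noise)
        for k in order:
            lr = learning_rate * max(0.1, 1.0 - step / total_steps)
            step += 1
            centre, ctx = pair_arr[k]
            targets = np.concatenate(([ctx], neg[k]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            h = w_in[centre]
            scores = _sigmoid(w_out[targets] @ h)
            g = (scores - labels) * lr
            grad_h = g @ w_out[targets]
            w_out[targets] -= np.outer(g, h)
            w_in[centre] -= grad_h

    return {tok: w_in[index[tok]].copy() for tok in vocab}
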