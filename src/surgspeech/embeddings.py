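"""Word embeddings trained on the training split of a corpus.

Two trainers are provided:

* :func:`train_word2vec` — skip-gram with negative sampling (SGNS):
  a word vector is trained to score true (center, context) pairs above
  randomly drawn negative contexts through a logistic loss.
* :func:`train_glove` — GloVe: symmetric windowed co-occurrence counts
  X(t, c) are factorized by minimizing the weighted least-squares
  objective sum f(X) * (w.wc + b + bc - ln X)^2 with the weighting
  f(x) = (x / x_max)^alpha capped at 1, via AdaGrad; the final vector
  for a term is the sum of its target and context vectors.

Both trainers run single-threaded on numpy and are deterministic under
their seed.  Corpora in this problem are small (hundreds of segments,
vocabularies of a few hundred terms), so no performance tricks beyond
vectorized negative sampling are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import TokenSeq

__all__ = [
    "EmbeddingModel",
    "train_word2vec",
    "train_glove",
    "cooccurrence_counts",
    "save_word2vec_format",
    "load_word2vec_format",
]


@dataclass
class EmbeddingModel:
    """Term -> dense vector mapping plus training provenance."""

    vectors: dict[str, np.ndarray]
    dim: int
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector for {term!r} has shape {vec.shape}, expected ({self.dim},)"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for {term!r} has non-finite entries")
            self.vectors[term] = vec

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vectors[a], self.vectors[b]
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        return float(va @ vb / denom) if denom > 0 else 0.0


def _build_vocab(
    token_seqs: Sequence[TokenSeq], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for seq in token_seqs:
        for tok in seq:
            counts[tok] = counts.get(tok, 0) + 1
    terms = sorted(t for t, c in counts.items() if c >= min_count)
    if not terms:
        raise ValueError(
            f"no term reaches min_count={min_count}; vocabulary is empty"
        )
    index = {t: i for i, t in enumerate(terms)}
    freq = np.array([counts[t] for t in terms], dtype=float)
    return terms, index, freq


def train_word2vec(
    train_tokens: Sequence[TokenSeq],
    d: int = 100,
    window: int = 5,
    negative: int = 5,
    epochs: int = 50,
    min_count: int = 1,
    lr: float = 0.05,
    seed: int = 0,
) -> EmbeddingModel:
    """Skip-gram with negative sampling on the given token sequences.

    Negative contexts are drawn from the unigram distribution raised to
    the 3/4 power.  The learning rate decays linearly to 1e-4 over all
    (epoch, pair) updates, mirroring standard SGNS training.
    """
    if not any(train_tokens):
        raise ValueError("cannot train word2vec on an empty corpus")
    terms, index, freq = _build_vocab(train_tokens, min_count)
    V = len(terms)
    rng = np.random.default_rng(seed)

    W = (rng.random((V, d)) - 0.5) / d  # target vectors
    C = np.zeros((V, d))  # context vectors

    noise = freq ** 0.75
    noise /= noise.sum()

    seqs = [[index[t] for t in seq if t in index] for seq in train_tokens]
    pairs: list[tuple[int, int]] = []
    for seq in seqs:
        for i, center in enumerate(seq):
            lo = max(0, i - window)
            hi = min(len(seq), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, seq[j]))
    if not pairs:
        raise ValueError("no skip-gram pairs (all sequences of length <= 1)")
    pairs_arr = np.array(pairs, dtype=int)

    total_updates = epochs * len(pairs_arr)
    done = 0
    min_lr = 1e-4
    for _ in range(epochs):
        order = rng.permutation(len(pairs_arr))
        neg = rng.choice(V, size=(len(pairs_arr), negative), p=noise)
        for k, row in enumerate(order):
            alpha = max(min_lr, lr * (1.0 - done / total_updates))
            center, ctx = pairs_arr[row]
            targets = np.concatenate(([ctx], neg[k]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            w = W[center]
            scores = C[targets] @ w
            g = (labels - 1.0 / (1.0 + np.exp(-scores))) * alpha
            W[center] = w + g @ C[targets]
            C[targets] += np.outer(g, w)
            done += 1

    vectors = {t: W[i].copy() for t, i in index.items()}
    params = dict(d=d, window=window, negative=negative, epochs=epochs,
                  min_count=min_count, lr=lr, seed=seed)
    return EmbeddingModel(vectors, d, "word2vec", params)


def cooccurrence_counts(
    token_seqs: Sequence[TokenSeq],
    index: Mapping[str, int],
    window: int,
) -> dict[tuple[int, int], float]:
    """Symmetric windowed co-occurrence counts X(t, c), unit-weighted."""
    X: dict[tuple[int, int], float] = {}
    for seq in token_seqs:
        ids = [index[t] for t in seq if t in index]
        for i, a in enumerate(ids):
            hi = min(len(ids), i + window + 1)
            for j in range(i + 1, hi):
                b = ids[j]
                X[(a, b)] = X.get((a, b), 0.0) + 1.0
                X[(b, a)] = X.get((b, a), 0.0) + 1.0
    return X


def train_glove(
    train_tokens: Sequence[TokenSeq],
    d: int = 100,
    window: int = 5,
    x_max: float = 100.0,
    alpha: float = 0.75,
    epochs: int = 50,
    lr: float = 0.05,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingModel:
    """GloVe on windowed co-occurrence counts, optimized with AdaGrad."""
    if not any(train_tokens):
        raise ValueError("cannot train glove on an empty corpus")
    terms, index, _ = _build_vocab(train_tokens, min_count)
    V = len(terms)
    X = cooccurrence_counts(train_tokens, index, window)
    if not X:
        raise ValueError("empty co-occurrence matrix (sequences too short)")

    ij = np.array(list(X.keys()), dtype=int)
    xs = np.array([X[tuple(k)] for k in ij], dtype=float)
    logx = np.log(xs)
    fx = np.minimum((xs / x_max) ** alpha, 1.0)

    rng = np.random.default_rng(seed)
    W = (rng.random((V, d)) - 0.5) / d
    Wc = (rng.random((V, d)) - 0.5) / d
    b = np.zeros(V)
    bc = np.zeros(V)
    gW = np.ones((V, d))
    gWc = np.ones((V, d))
    gb = np.ones(V)
    gbc = np.ones(V)

    for _ in range(epochs):
        order = rng.permutation(len(ij))
        for k in order:
            i, j = ij[k]
            diff = W[i] @ Wc[j] + b[i] + bc[j] - logx[k]
            coef = fx[k] * diff
            grad_wi = coef * Wc[j]
            grad_wj = coef * W[i]
            W[i] -= lr * grad_wi / np.sqrt(gW[i])
            Wc[j] -= lr * grad_wj / np.sqrt(gWc[j])
            gW[i] += grad_wi ** 2
            gWc[j] += grad_wj ** 2
            b[i] -= lr * coef / np.sqrt(gb[i])
            bc[j] -= lr * coef / np.sqrt(gbc[j])
            gb[i] += coef ** 2
            gbc[j] += coef ** 2

    vectors = {t: (W[i] + Wc[i]).copy() for t, i in index.items()}
    params = dict(d=d, window=window, x_max=x_max, alpha=alpha,
                  epochs=epochs, lr=lr, min_count=min_count, seed=seed)
    return EmbeddingModel(vectors, d, "glove", params)


def save_word2vec_format(model: EmbeddingModel, path: str | Path) -> None:
    """Write the standard word2vec text format: "V d" header, then one
    "term v1 ... vd" line per term."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vectors)} {model.dim}\n")
        for term in sorted(model.vectors):
            vals = " ".join(repr(float(v)) for v in model.vectors[term])
            fh.write(f"{term} {vals}\n")


def load_word2vec_format(path: str | Path, method: str = "loaded") -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != n:
        raise ValueError(f"header declares {n} terms, file has {len(vectors)}")
    return EmbeddingModel(vectors, d, method)
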