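"""Segment-level feature extraction: BOW, TF-iDF, and embedding averages.

All fitting (vocabulary, document frequencies, embedding training)
happens on training token sequences only; transforming unseen segments
never updates the fitted state, so there is no train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import TokenSeq

__all__ = [
    "VocabularyModel",
    "FeatureMatrix",
    "fit_vocabulary",
    "bow_transform",
    "tfidf_transform",
    "embed_segments",
    "make_extractor",
    "FeatureExtractor",
    "BowExtractor",
    "TfidfExtractor",
    "EmbeddingExtractor",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("bow", "tfidf", "word2vec", "glove")


@dataclass
class FeatureMatrix:
    """Segment-aligned numeric features with a provenance tag."""

    values: np.ndarray
    extractor: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",",
                   header=self.extractor, comments="# ")


@dataclass
class VocabularyModel:
    """Term -> column mapping with per-term document frequencies."""

    index: dict[str, int]
    df: dict[str, int]
    n_docs: int

    def __post_init__(self) -> None:
        cols = sorted(self.index.values())
        if cols != list(range(len(self.index))):
            raise ValueError("vocabulary indices must be 0..V-1 without gaps")
        for term, d in self.df.items():
            if not 1 <= d <= self.n_docs:
                raise ValueError(f"df({term!r})={d} outside 1..{self.n_docs}")

    @property
    def size(self) -> int:
        return len(self.index)


def fit_vocabulary(train_tokens: Sequence[TokenSeq]) -> VocabularyModel:
    """Collect all distinct training terms (sorted lexicographically for
    reproducibility) and per-segment document frequencies."""
    terms: set[str] = set()
    for seq in train_tokens:
        terms.update(seq)
    if not terms:
        raise ValueError("cannot fit a vocabulary: all token sequences empty")
    index = {t: i for i, t in enumerate(sorted(terms))}
    df = {t: 0 for t in index}
    for seq in train_tokens:
        for t in set(seq):
            df[t] += 1
    return VocabularyModel(index=index, df=df, n_docs=len(train_tokens))


def bow_transform(
    tokens_list: Sequence[TokenSeq], vocab: VocabularyModel
) -> FeatureMatrix:
    """Term-count matrix; out-of-vocabulary tokens are ignored."""
    X = np.zeros((len(tokens_list), vocab.size))
    for i, seq in enumerate(tokens_list):
        for tok in seq:
            j = vocab.index.get(tok)
            if j is not None:
                X[i, j] += 1.0
    return FeatureMatrix(X, "bow")


def tfidf_transform(
    tokens_list: Sequence[TokenSeq], vocab: VocabularyModel
) -> FeatureMatrix:
    """TF-iDF with smoothed idf and L2 row normalization.

    idf(t) = ln((1 + n_docs) / (1 + df(t))) + 1; rows with no known
    terms stay zero.  The smoothing treats every term as if seen in one
    extra pseudo-document, so unseen-at-transform-time terms cannot blow
    up the weight.
    """
    counts = bow_transform(tokens_list, vocab).values
    idf = np.ones(vocab.size)
    for term, j in vocab.index.items():
        idf[j] = np.log((1 + vocab.n_docs) / (1 + vocab.df[term])) + 1.0
    X = counts * idf
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return FeatureMatrix(X / norms, "tfidf(smooth_idf,l2)")


def embed_segments(
    tokens_list: Sequence[TokenSeq], emb: "EmbeddingModel"
) -> FeatureMatrix:
    """Segment vector = unweighted mean of its in-vocabulary word vectors.

    Segments with no known tokens map to the zero vector.  The mean is
    order-invariant, matching the per-segment (bag-of-vectors) view the
    classifiers take.
    """
    X = np.zeros((len(tokens_list), emb.dim))
    for i, seq in enumerate(tokens_list):
        vecs = [emb.vectors[t] for t in seq if t in emb.vectors]
        if vecs:
            X[i] = np.mean(vecs, axis=0)
    return FeatureMatrix(X, f"embedding({emb.method})")


# --------------------------------------------------------------------------
# Uniform extractor interface used by the experiment pipeline and CV
# --------------------------------------------------------------------------


class FeatureExtractor:
    """fit-on-train / transform-anywhere interface over the extractors."""

    name: str = ""

    def fit(self, train_tokens: Sequence[TokenSeq]) -> "FeatureExtractor":
        raise NotImplementedError

    def transform(self, tokens_list: Sequence[TokenSeq]) -> FeatureMatrix:
        raise NotImplementedError


class BowExtractor(FeatureExtractor):
    name = "bow"

    def __init__(self) -> None:
        self.vocab: VocabularyModel | None = None

    def fit(self, train_tokens: Sequence[TokenSeq]) -> "BowExtractor":
        self.vocab = fit_vocabulary(train_tokens)
        return self

    def transform(self, tokens_list: Sequence[TokenSeq]) -> FeatureMatrix:
        assert self.vocab is not None, "extractor not fitted"
        return bow_transform(tokens_list, self.vocab)


class TfidfExtractor(FeatureExtractor):
    name = "tfidf"

    def __init__(self) -> None:
        self.vocab: VocabularyModel | None = None

    def fit(self, train_tokens: Sequence[TokenSeq]) -> "TfidfExtractor":
        self.vocab = fit_vocabulary(train_tokens)
        return self

    def transform(self, tokens_list: Sequence[TokenSeq]) -> FeatureMatrix:
        assert self.vocab is not None, "extractor not fitted"
        return tfidf_transform(tokens_list, self.vocab)


class EmbeddingExtractor(FeatureExtractor):
    """Word2Vec or GloVe embeddings trained on the training split."""

    def __init__(self, method: str = "word2vec", seed: int = 0, **params) -> None:
        if method not in ("word2vec", "glove"):
            raise ValueError(f"unknown embedding method {method!r}")
        self.name = method
        self.method = method
        self.seed = seed
        self.params = params
        self.model: "EmbeddingModel | None" = None

    def fit(self, train_tokens: Sequence[TokenSeq]) -> "EmbeddingExtractor":
        from . import embeddings

        if self.method == "word2vec":
            self.model = embeddings.train_word2vec(
                train_tokens, seed=self.seed, **self.params
            )
        else:
            self.model = embeddings.train_glove(
                train_tokens, seed=self.seed, **self.params
            )
        return self

    def transform(self, tokens_list: Sequence[TokenSeq]) -> FeatureMatrix:
        assert self.model is not None, "extractor not fitted"
        return embed_segments(tokens_list, self.model)


def make_extractor(name: str, seed: int = 0, **params) -> FeatureExtractor:
    if name == "bow":
        return BowExtractor()
    if name == "tfidf":
        return TfidfExtractor()
    if name in ("word2vec", "glove"):
        return EmbeddingExtractor(method=name, seed=seed, **params)
    raise ValueError(f"unknown feature set {name!r}; choose from {FEATURE_NAMES}")


from .embeddings import EmbeddingModel  # noqa: E402  (re-export for typing)
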