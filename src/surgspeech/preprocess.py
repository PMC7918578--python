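"""Text pre-processing: normalization, tokenization, stop words, stemming.

The pipeline applied to every transcript segment before feature
extraction is the composition

    normalize -> tokenize -> remove_stopwords -> stem

Normalization lowercases and strips punctuation, markup tags and special
characters while keeping letters (including accented letters), digits
and word-internal underscores; accents are deliberately preserved.
Stemming is pluggable (``none``, ``snowball-es``, ``snowball-en``) with
``none`` as the default, since the synthetic corpora use abstract tokens
on which stemming is a no-op; Spanish transcripts use ``snowball-es``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

from ._snowball import english_stem, spanish_stem

__all__ = [
    "PreprocessConfig",
    "normalize_text",
    "tokenize",
    "remove_stopwords",
    "stem",
    "preprocess",
    "load_stoplist",
    "STEMMERS",
]

TokenSeq = list[str]

STEMMERS: dict[str, Callable[[str], str]] = {
    "none": lambda tok: tok,
    "snowball-es": spanish_stem,
    "snowball-en": english_stem,
}

_TAG_RE = re.compile(r"<[^>]*>")
_NONWORD_RE = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_text(text: str) -> str:
    """Lowercase and strip punctuation/tags/special characters."""
    text = _TAG_RE.sub(" ", text)
    text = _NONWORD_RE.sub(" ", text)
    return " ".join(text.lower().split())


def tokenize(text: str) -> TokenSeq:
    """Split normalized text on whitespace, preserving order."""
    return text.split()


def remove_stopwords(tokens: Iterable[str], stoplist: set[str]) -> TokenSeq:
    return [tok for tok in tokens if tok not in stoplist]


def stem(tokens: Iterable[str], stemmer_id: str = "none") -> TokenSeq:
    try:
        fn = STEMMERS[stemmer_id]
    except KeyError:
        raise ValueError(
            f"unknown stemmer {stemmer_id!r}; choose from {sorted(STEMMERS)}"
        ) from None
    return [fn(tok) for tok in tokens]


def load_stoplist(source: str | Path | None) -> set[str]:
    """Resolve a stop-word list.

    ``None`` or ``"none"`` gives the empty list (used for synthetic
    corpora); ``"spanish"`` loads the bundled Spanish list;
    ``"english"`` uses scikit-learn's built-in English list; anything
    else is read as a path to a plain-text file, one word per line.
    """
    if source is None or source == "none":
        return set()
    if source == "spanish":
        text = (
            resources.files("surgspeech") / "data" / "stopwords_es.txt"
        ).read_text(encoding="utf-8")
        return {line.strip() for line in text.splitlines() if line.strip()}
    if source == "english":
        from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

        return set(ENGLISH_STOP_WORDS)
    return {
        line.strip()
        for line in Path(source).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


@dataclass(frozen=True)
class PreprocessConfig:
    """Names the stop list and stemmer applied to every segment."""

    stoplist: str | None = None
    stemmer: str = "none"

    def __post_init__(self) -> None:
        if self.stemmer not in STEMMERS:
            raise ValueError(
                f"unknown stemmer {self.stemmer!r}; choose from {sorted(STEMMERS)}"
            )

    def resolved_stoplist(self) -> set[str]:
        return load_stoplist(self.stoplist)


def preprocess(text: str, config: PreprocessConfig | None = None) -> TokenSeq:
    """Full pipeline: normalize, tokenize, drop stop words, stem."""
    config = config or PreprocessConfig()
    tokens = tokenize(normalize_text(text))
    tokens = remove_stopwords(tokens, config.resolved_stoplist())
    return stem(tokens, config.stemmer)


def preprocess_texts(
    texts: Iterable[str], config: PreprocessConfig | None = None
) -> list[TokenSeq]:
    config = config or PreprocessConfig()
    stoplist = config.resolved_stoplist()
    fn = STEMMERS[config.stemmer]
    out = []
    for text in texts:
        toks = remove_stopwords(tokenize(normalize_text(text)), stoplist)
        out.append([fn(t) for t in toks])
    return out
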