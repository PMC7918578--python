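"""Seeded generator of labelled transcript corpora.

The study corpus (transcribed surgeon speech from 15 educational
laparoscopic cholecystectomy videos) is not publicly deposited, so this
module generates corpora with the same statistical structure, making
every downstream stage testable:

* each video is a monotone walk over phases 1..7 (phases may be skipped,
  never revisited), with "extra" pseudo-phase segments (label 8) randomly
  interleaved — conversation that is not part of the surgical sequence;
* each phase owns an abstract keyword vocabulary; a configurable fraction
  of a phase pair's vocabulary can be shared to emulate lexical
  confusability between phases (e.g. "dissect" occurring in both Calot's
  triangle dissection and gallbladder dissection);
* keywords may be swapped for same-phase synonyms, and generic filler
  tokens play the role of function words.

Tokens are abstract (``p4_kw_07``), not real Spanish: the recognition
method is language-agnostic once text is tokenized, and this avoids
fabricating clinical prose.  All generation is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, CountsTable, Segment

__all__ = [
    "SyntheticConfig",
    "phase_vocabulary",
    "generate_phase_timeline",
    "generate_segment_text",
    "generate_corpus",
    "corpus_from_counts",
]

_SURGICAL_PHASES = tuple(range(1, 8))
EXTRA = 8

_N_FILLER = 12
_FILLERS = tuple(f"fill_{i:02d}" for i in range(_N_FILLER))
_N_EXTRA_VOCAB = 40
_EXTRA_VOCAB = tuple(f"x_kw_{i:02d}" for i in range(_N_EXTRA_VOCAB))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the corpus generator.

    segments_per_phase
        Mean number of segments per surgical phase per video; either a
        single float or a mapping phase -> mean.  A mapping entry for
        phase 8 sets the mean number of extra segments inserted per
        video (overriding ``extra_insertion_prob``).  Counts are drawn
        as ``1 + Poisson(mean - 1)`` so a mean of 1 is exact.
    overlap
        Mapping (phase_a, phase_b) -> fraction in [0, 1] of phase_b's
        keyword vocabulary replaced by phase_a keywords.
    synonym_rate
        Probability that an emitted keyword is replaced by its same-phase
        synonym token.
    extra_insertion_prob
        Probability of inserting an extra-phase segment in each gap
        between two consecutive surgical segments.
    phase_skip_prob
        Probability that each of phases 1..7 is absent from a video.
    filler_rate
        Per-token probability of emitting a generic filler token instead
        of a phase keyword.
    phrase_len
        Inclusive (min, max) token count per segment.
    """

    n_videos: int = 15
    segments_per_phase: float | Mapping[int, float] = 5.0
    vocab_size_per_phase: int = 20
    overlap: Mapping[tuple[int, int], float] = field(default_factory=dict)
    synonym_rate: float = 0.1
    extra_insertion_prob: float = 0.3
    phase_skip_prob: float = 0.05
    filler_rate: float = 0.25
    phrase_len: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "synonym_rate": self.synonym_rate,
            "extra_insertion_prob": self.extra_insertion_prob,
            "phase_skip_prob": self.phase_skip_prob,
            "filler_rate": self.filler_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for pair, f in self.overlap.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"overlap{pair} must be in [0, 1], got {f}")
        if self.phrase_len[0] < 1 or self.phrase_len[1] < self.phrase_len[0]:
            raise ValueError(f"invalid phrase_len {self.phrase_len}")
        if self.vocab_size_per_phase < 1:
            raise ValueError("vocab_size_per_phase must be >= 1")
        if self.n_videos < 1:
            raise ValueError("n_videos must be >= 1")

    def mean_segments(self, phase: int) -> float | None:
        if isinstance(self.segments_per_phase, Mapping):
            val = self.segments_per_phase.get(phase)
            return None if val is None else float(val)
        if phase == EXTRA:
            return None
        return float(self.segments_per_phase)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def phase_vocabulary(phase: int, config: SyntheticConfig) -> tuple[str, ...]:
    """Keyword inventory of one phase, after applying vocabulary overlap.

    Phase 8 always uses the generic conversational vocabulary.  For a
    surgical phase ``b``, an ``overlap[(a, b)] = f`` entry replaces the
    last ``round(f * V)`` of b's own keywords with the first keywords of
    phase ``a``, so the shared fraction is exactly ``f`` up to rounding.
    """
    if phase == EXTRA:
        return _EXTRA_VOCAB
    size = config.vocab_size_per_phase
    own = [f"p{phase}_kw_{i:02d}" for i in range(size)]
    for (a, b), frac in config.overlap.items():
        if b != phase or frac <= 0.0:
            continue
        n_shared = int(round(frac * size))
        donor = [f"p{a}_kw_{i:02d}" for i in range(n_shared)]
        own = own[: size - n_shared] + donor
    return tuple(own)


def _synonym(token: str) -> str:
    return token.replace("_kw_", "_syn_")


def generate_phase_timeline(
    config: SyntheticConfig, video_id: str, rng: np.random.Generator
) -> list[int]:
    """Phase-label sequence for one video.

    Non-extra labels form a non-decreasing walk over phases 1..7: each
    phase is skipped with ``phase_skip_prob``, otherwise contributes a
    contiguous block of segments, and is never revisited.  Extra labels
    are then inserted into the gaps between consecutive surgical
    segments (or with count-based placement when a phase-8 mean is
    configured).
    """
    base: list[int] = []
    for phase in _SURGICAL_PHASES:
        if rng.random() < config.phase_skip_prob:
            continue
        mean = config.mean_segments(phase)
        assert mean is not None and mean >= 1.0
        count = 1 + int(rng.poisson(mean - 1.0))
        base.extend([phase] * count)
    if not base:  # every phase skipped: force one segment so the video exists
        base = [int(rng.integers(1, 8))]

    extra_mean = config.mean_segments(EXTRA)
    if extra_mean is not None:
        n_extra = int(rng.poisson(extra_mean))
        timeline = list(base)
        for _ in range(n_extra):
            pos = int(rng.integers(0, len(timeline) + 1))
            timeline.insert(pos, EXTRA)
        return timeline

    timeline = [base[0]]
    for label in base[1:]:
        if rng.random() < config.extra_insertion_prob:
            timeline.append(EXTRA)
        timeline.append(label)
    return timeline


def generate_segment_text(
    phase: int, config: SyntheticConfig, rng: np.random.Generator
) -> str:
    """One synthetic utterance for a phase, as a space-joined token string."""
    vocab = phase_vocabulary(phase, config)
    lo, hi = config.phrase_len
    length = int(rng.integers(lo, hi + 1))
    tokens: list[str] = []
    for _ in range(length):
        if phase != EXTRA and rng.random() < config.filler_rate:
            tokens.append(_FILLERS[int(rng.integers(0, _N_FILLER))])
            continue
        tok = vocab[int(rng.integers(0, len(vocab)))]
        if phase != EXTRA and rng.random() < config.synonym_rate:
            tok = _synonym(tok)
        tokens.append(tok)
    return " ".join(tokens)


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Generate a full corpus of ``n_videos`` labelled videos."""
    rng = np.random.default_rng(config.seed)
    segments: list[Segment] = []
    width = max(2, len(str(config.n_videos)))
    for v in range(1, config.n_videos + 1):
        vid = f"v{v:0{width}d}"
        timeline = generate_phase_timeline(config, vid, rng)
        for idx, phase in enumerate(timeline):
            text = generate_segment_text(phase, config, rng)
            segments.append(Segment(vid, idx, text, phase))
    return Corpus(segments)


def corpus_from_counts(
    table: CountsTable, config: SyntheticConfig, seed: int | None = None
) -> Corpus:
    """Generate a corpus whose per-video, per-phase counts match ``table``
    exactly.

    Surgical phases appear as contiguous blocks in phase order; the
    video's extra segments are inserted at uniformly random gaps.  Used
    to rebuild a corpus with the study's exact sample accounting.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    segments: list[Segment] = []
    for vid, row in table.counts.iterrows():
        base: list[int] = []
        for phase in _SURGICAL_PHASES:
            base.extend([phase] * int(row[phase]))
        timeline = list(base)
        for _ in range(int(row[EXTRA])):
            pos = int(rng.integers(0, len(timeline) + 1))
            timeline.insert(pos, EXTRA)
        for idx, phase in enumerate(timeline):
            text = generate_segment_text(phase, config, rng)
            segments.append(Segment(str(vid), idx, text, phase))
    return Corpus(segments)
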