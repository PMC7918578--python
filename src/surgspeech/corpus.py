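"""Transcript corpus data model and I/O.

A corpus is an ordered collection of transcribed speech segments from
surgical educational videos of laparoscopic cholecystectomy (LC).  Each
segment carries the id of the video it came from, its 0-based temporal
index within that video, the transcript text, and a phase label 1-8:
phases 1-7 are the ordered LC phases (preparation; Calot's triangle
dissection; cystic duct and artery clipping and cutting; gallbladder
dissection; gallbladder extraction; cleaning and coagulation; suturing
and port removal) and 8 is the "extra" pseudo-phase collecting operating
room conversation unrelated to any surgical phase.

Corpora are stored as UTF-8 JSON-lines files, one segment per line with
keys ``video_id``, ``index``, ``text`` and ``phase``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

N_PHASES = 8
PHASES = tuple(range(1, N_PHASES + 1))

PHASE_NAMES = {
    1: "preparation",
    2: "calot triangle dissection",
    3: "clipping and cutting",
    4: "gallbladder dissection",
    5: "gallbladder extraction",
    6: "cleaning and coagulation",
    7: "suturing and port removal",
    8: "extra",
}


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid segment data."""


def _check_phase(phase: int) -> int:
    phase = int(phase)
    if phase not in PHASES:
        raise CorpusError(f"phase must be in 1..{N_PHASES}, got {phase}")
    return phase


@dataclass(frozen=True)
class Segment:
    """One transcribed utterance: the unit of classification."""

    video_id: str
    index: int
    text: str
    phase: int

    def __post_init__(self) -> None:
        if not str(self.text).strip():
            raise CorpusError(
                f"segment ({self.video_id}, {self.index}) has empty text"
            )
        if self.index < 0:
            raise CorpusError(f"segment index must be >= 0, got {self.index}")
        _check_phase(self.phase)


@dataclass
class Corpus:
    """Ordered, video-grouped collection of segments.

    Within each video, indices must be consecutive ``0..T-1`` in order of
    appearance; video order is the order of first appearance.
    """

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        next_index: dict[str, int] = {}
        for seg in self.segments:
            expected = next_index.get(seg.video_id, 0)
            if seg.index != expected:
                raise CorpusError(
                    f"video {seg.video_id!r}: expected index {expected}, "
                    f"got {seg.index} (indices must be consecutive from 0)"
                )
            next_index[seg.video_id] = expected + 1

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Corpus) and self.segments == other.segments

    @property
    def video_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.video_id, None)
        return list(seen)

    def video(self, video_id: str) -> list[Segment]:
        return [s for s in self.segments if s.video_id == video_id]

    def by_video(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.video_id, []).append(seg)
        return out

    def labels(self) -> np.ndarray:
        """Phase labels in corpus order."""
        return np.array([s.phase for s in self.segments], dtype=int)

    def texts(self) -> list[str]:
        return [s.text for s in self.segments]

    def label_sequences(self) -> list[list[int]]:
        """Per-video phase sequences, in video order."""
        return [[s.phase for s in segs] for segs in self.by_video().values()]


@dataclass
class CountsTable:
    """Video x phase table of segment counts with marginals.

    ``counts`` is indexed by video id (rows) and phase 1-8 (columns).
    ``test_video_ids`` optionally flags the videos reserved for testing.
    """

    counts: pd.DataFrame
    test_video_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise CorpusError("counts must be non-negative")
        self.counts = self.counts.astype(int)
        self.counts.columns = [int(c) for c in self.counts.columns]

    @property
    def video_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def phase_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.columns = [f"phase_{p}" if p < 8 else "extra" for p in df.columns]
        df["total"] = self.video_totals
        total = df.sum(axis=0)
        total.name = "total"
        pd.concat([df, total.to_frame().T]).to_csv(path, index_label="video")


def load_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus file, preserving record order."""
    segments: list[Segment] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            try:
                seg = Segment(
                    video_id=str(rec["video_id"]),
                    index=int(rec["index"]),
                    text=str(rec["text"]),
                    phase=int(rec["phase"]),
                )
            except KeyError as exc:
                raise CorpusError(f"{path}:{lineno}: missing field {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            segments.append(seg)
    return Corpus(segments)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as UTF-8 JSON lines; round-trips bit-exact."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seg in corpus:
            rec = {
                "video_id": seg.video_id,
                "index": seg.index,
                "text": seg.text,
                "phase": seg.phase,
            }
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=False))
            fh.write("\n")


def split_corpus(
    corpus: Corpus, test_video_ids: Iterable[str]
) -> tuple[Corpus, Corpus]:
    """Partition a corpus by whole videos into (train, test).

    Splitting is always at video granularity so that no video contributes
    segments to both sides, mirroring the held-out-video evaluation design.
    """
    test_ids = set(test_video_ids)
    unknown = test_ids - set(corpus.video_ids)
    if unknown:
        raise CorpusError(f"unknown test video ids: {sorted(unknown)}")
    train = [s for s in corpus.segments if s.video_id not in test_ids]
    test = [s for s in corpus.segments if s.video_id in test_ids]
    return Corpus(train), Corpus(test)


def phase_counts(corpus: Corpus) -> CountsTable:
    """Tabulate segments per (video, phase) with marginals."""
    vids = corpus.video_ids
    df = pd.DataFrame(0, index=vids, columns=list(PHASES), dtype=int)
    for seg in corpus:
        df.loc[seg.video_id, seg.phase] += 1
    return CountsTable(df)


# Per-video, per-phase segment counts of the 15-video study corpus
# (phases 1-7 then the extra pseudo-phase).  Videos 1 and 2 are the
# held-out test videos.
_STUDY_COUNTS: dict[str, Sequence[int]] = {
    "1": (4, 5, 10, 1, 3, 1, 1, 11),
    "2": (5, 2, 3, 1, 2, 3, 2, 4),
    "3": (9, 7, 9, 2, 7, 9, 2, 18),
    "4": (1, 6, 6, 2, 2, 1, 1, 3),
    "5": (9, 5, 6, 0, 1, 3, 4, 16),
    "6": (0, 3, 12, 4, 4, 5, 0, 6),
    "7": (1, 4, 5, 2, 1, 5, 0, 8),
    "8": (14, 28, 12, 13, 14, 11, 8, 61),
    "9": (2, 10, 5, 6, 2, 2, 0, 12),
    "10": (5, 6, 3, 3, 2, 0, 1, 3),
    "11": (0, 2, 3, 1, 1, 1, 0, 4),
    "12": (0, 7, 7, 5, 1, 3, 0, 6),
    "13": (0, 5, 6, 1, 1, 1, 0, 1),
    "14": (4, 6, 7, 1, 2, 0, 2, 7),
    "15": (5, 6, 10, 0, 7, 9, 1, 18),
}

TEST_VIDEO_IDS = frozenset({"1", "2"})


def table2_fixture() -> CountsTable:
    """The study corpus sample-count table (15 videos x 8 phases).

    Returns the per-video distribution of transcribed segments over the
    seven LC phases and the extra pseudo-phase, with videos 1 and 2
    flagged as the held-out test videos.
    """
    df = pd.DataFrame.from_dict(_STUDY_COUNTS, orient="index", columns=list(PHASES))
    return CountsTable(df, test_video_ids=TEST_VIDEO_IDS)
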