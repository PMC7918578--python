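"""Classifier-coupled hidden Markov model over the 8 phase states.

The surgical phases of a video form a hidden state sequence with strong
temporal structure (phases 1-7 progress monotonically; conversation can
interleave anywhere).  Because training sequences are fully labelled,
the transition matrix and initial distribution are estimated by
supervised counting with additive (Laplace) smoothing — no Baum-Welch
is needed.  Per-segment classifier posteriors are converted to emission
scores, and each test video is decoded independently with the Viterbi
algorithm in log space.

Emission modes:

* ``posterior`` — b_t(s) = max(p_t(s), floor): the decoder maximizes
  the product of smoothed posteriors along the path;
* ``scaled_likelihood`` (default) — b_t(s) = max(p_t(s)/prior(s), floor):
  dividing by the training class prior converts the discriminative
  posterior into a quantity proportional to the class-conditional
  likelihood, the standard coupling for hybrid classifier/HMM systems.

Phases never seen by the classifier emit the floor everywhere, so the
decoder can still pass through them if transitions demand it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, N_PHASES
from .classify import ClassifierModel, predict_posteriors

__all__ = [
    "TransitionModel",
    "EmissionSeq",
    "DecodedTimeline",
    "estimate_transitions",
    "posteriors_to_emissions",
    "viterbi",
    "decode_corpus",
]

EXTRA_STATE = N_PHASES - 1  # 0-based state index of the pseudo-phase


@dataclass
class TransitionModel:
    """8-state row-stochastic transition matrix + initial distribution."""

    A: np.ndarray
    pi: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.A.shape != (N_PHASES, N_PHASES) or self.pi.shape != (N_PHASES,):
            raise ValueError("transition model must be 8x8 with a length-8 pi")
        if (self.A < 0).any() or (self.pi < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")

    def boost_extra(self, boost: float) -> "TransitionModel":
        """Add transition mass into and out of the extra pseudo-phase,
        then renormalize — loosening the restriction on entering the
        conversation state from any phase."""
        if boost < 0:
            raise ValueError("boost must be >= 0")
        A = self.A.copy()
        A[:, EXTRA_STATE] += boost
        A[EXTRA_STATE, :] += boost
        A /= A.sum(axis=1, keepdims=True)
        return TransitionModel(A, self.pi.copy(), self.alpha)

    def to_csv(self, path: str | Path) -> None:
        states = [f"phase_{p}" if p < 8 else "extra" for p in range(1, 9)]
        df = pd.DataFrame(self.A, index=states, columns=states)
        df.loc["initial"] = self.pi
        df.to_csv(path, index_label="from")


@dataclass
class EmissionSeq:
    """Per-video T x 8 matrix of strictly positive emission scores."""

    scores: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_PHASES:
            raise ValueError("emission scores must be T x 8")
        if not np.all(np.isfinite(self.scores)) or (self.scores <= 0).any():
            raise ValueError("emission scores must be positive and finite")


@dataclass
class DecodedTimeline:
    """Viterbi output for one video: phases (1-based) and path log-score."""

    video_id: str
    phases: list[int]
    log_score: float

    def to_records(self, truth: Sequence[int] | None = None) -> pd.DataFrame:
        data = {"video_id": self.video_id,
                "index": np.arange(len(self.phases)),
                "predicted": self.phases}
        if truth is not None:
            data["truth"] = list(truth)
        return pd.DataFrame(data)


def estimate_transitions(
    label_sequences: Sequence[Sequence[int]], alpha: float = 0.01
) -> TransitionModel:
    """Supervised transition/initial estimation with additive smoothing.

    A[s, s'] = (count(s->s') + alpha) / (count(s->.) + 8 * alpha) and
    pi[s] = (count(first = s) + alpha) / (n_sequences + 8 * alpha).
    With alpha = 0, rows for states never left are set uniform with a
    warning (they carry no information).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    seqs = [list(s) for s in label_sequences if len(s) > 0]
    if not seqs:
        raise ValueError("need at least one non-empty label sequence")
    trans = np.zeros((N_PHASES, N_PHASES))
    first = np.zeros(N_PHASES)
    for seq in seqs:
        first[seq[0] - 1] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            trans[a - 1, b - 1] += 1

    A = trans + alpha
    row = A.sum(axis=1)
    zero_rows = row == 0.0
    if zero_rows.any():
        warnings.warn(
            f"states {np.flatnonzero(zero_rows) + 1} never leave in training; "
            "their transition rows are set uniform",
            stacklevel=2,
        )
        A[zero_rows] = 1.0
        row = A.sum(axis=1)
    A /= row[:, None]

    pi = first + alpha
    if pi.sum() == 0.0:
        pi[:] = 1.0
    pi /= pi.sum()
    return TransitionModel(A, pi, alpha)


def posteriors_to_emissions(
    posteriors: np.ndarray,
    classes: Sequence[int],
    class_priors: Sequence[float] | None = None,
    mode: str = "scaled_likelihood",
    floor: float = 1e-6,
) -> EmissionSeq:
    """Map classifier posteriors (columns = ``classes``) onto 8-state
    emission scores.

    ``classes`` are the 1-based phases in the classifier's column order;
    phases it never saw emit the floor.  In ``scaled_likelihood`` mode
    each posterior is divided by its class prior before flooring.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != len(classes):
        raise ValueError("posterior shape does not match the class list")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if mode not in ("posterior", "scaled_likelihood"):
        raise ValueError(f"unknown emission mode {mode!r}")
    scores = np.full((post.shape[0], N_PHASES), floor)
    if mode == "scaled_likelihood":
        if class_priors is None:
            raise ValueError("scaled_likelihood mode needs class priors")
        priors = np.asarray(class_priors, dtype=float)
        if (priors <= 0).any():
            raise ValueError("class priors must be strictly positive")
        values = post / priors
    else:
        values = post
    for col, phase in enumerate(classes):
        scores[:, phase - 1] = np.maximum(values[:, col], floor)
    return EmissionSeq(scores, mode)


def viterbi(
    tm: TransitionModel, em: EmissionSeq, video_id: str = ""
) -> DecodedTimeline:
    """Most probable state path in log space.

    Maximizes ln pi[s1] + ln b_1(s1) + sum_t (ln A[s_{t-1}, s_t] +
    ln b_t(s_t)).  Ties are broken toward the lowest state index at
    every backtracking step (np.argmax returns the first maximum).
    """
    B = em.scores
    T = B.shape[0]
    if T == 0:
        raise ValueError("cannot decode an empty emission sequence")
    with np.errstate(divide="ignore"):  # zero transition probs -> -inf
        logA = np.log(tm.A)
        logpi = np.log(tm.pi)
    logB = np.log(B)

    delta = logpi + logB[0]
    back = np.zeros((T, N_PHASES), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[s, s'] = score ending s then s'
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(N_PHASES)] + logB[t]

    last = int(np.argmax(delta))
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    path.reverse()
    return DecodedTimeline(
        video_id=video_id,
        phases=[s + 1 for s in path],
        log_score=float(delta[last]),
    )


def decode_corpus(
    model: ClassifierModel,
    tm: TransitionModel,
    features_by_video: dict[str, np.ndarray],
    mode: str = "scaled_likelihood",
    floor: float = 1e-6,
) -> list[DecodedTimeline]:
    """Decode each video independently from its segment features.

    ``features_by_video`` maps video id to the T x d feature matrix of
    its segments in temporal order, produced by the model's
    training-time preprocessing and extraction pipeline.
    """
    timelines = []
    for vid, X in features_by_video.items():
        post = predict_posteriors(model, X)
        em = posteriors_to_emissions(
            post, model.classes, model.class_priors, mode=mode, floor=floor
        )
        timelines.append(viterbi(tm, em, video_id=vid))
    return timelines
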