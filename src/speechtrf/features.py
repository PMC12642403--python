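"""Predictor tracks and sublexical (phoneme n-gram) features.

A predictor track is a uniformly sampled time series aligned to a neural
response: either an impulse train (unit or feature-scaled spikes at event
onsets) or a continuous signal (acoustic band envelopes).  Sublexical
surprisal/entropy come from a fixed-order phoneme model applied to the
running phoneme sequence, crossing word boundaries by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .info import entropy as _entropy
from .info import surprisal as _surprisal
from .lexicon import EventTable
from .ngram import NGramModel, VocabularyError

__all__ = [
    "PredictorTrack",
    "FeatureSequence",
    "sample_index",
    "onset_tracks",
    "feature_track",
    "sublexical_features",
]


@dataclass
class PredictorTrack:
    """Named, uniformly sampled predictor aligned to a response."""

    name: str
    fs: float
    values: np.ndarray
    kind: str = "impulse"  # "impulse" | "continuous"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.kind not in ("impulse", "continuous"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureSequence:
    """Per-phoneme-event information values for one context model.

    ``cohort_entropy`` is None for the sublexical model, where no candidate
    word set is defined.  ``fallback`` flags events covered by the uniform
    out-of-cohort fallback.
    """

    surprisal: np.ndarray
    phoneme_entropy: np.ndarray
    cohort_entropy: np.ndarray | None = None
    base: float = math.e
    fallback: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.surprisal = np.asarray(self.surprisal, dtype=float)
        self.phoneme_entropy = np.asarray(self.phoneme_entropy, dtype=float)
        n = len(self.surprisal)
        if len(self.phoneme_entropy) != n:
            raise ValueError("feature columns must have equal length")
        if self.cohort_entropy is not None:
            self.cohort_entropy = np.asarray(self.cohort_entropy, dtype=float)
            if len(self.cohort_entropy) != n:
                raise ValueError("feature columns must have equal length")
        if self.fallback is None:
            self.fallback = np.zeros(n, dtype=bool)
        if np.any(self.surprisal < 0) or np.any(self.phoneme_entropy < 0):
            raise ValueError("surprisal and entropy must be nonnegative")

    def __len__(self) -> int:
        return len(self.surprisal)


def sample_index(t: float, fs: float) -> int:
    """Nearest sample to time ``t``; exact ties resolve to the earlier sample."""
    return int(math.ceil(t * fs - 0.5))


def _n_samples(events: EventTable, fs: float) -> int:
    return max(int(round(events.duration * fs)), 1)


def onset_tracks(
    events: EventTable, fs: float
) -> tuple[PredictorTrack, PredictorTrack]:
    """Unit-impulse word-onset and (non-initial) phoneme-onset tracks.

    Word-initial phonemes appear only in the word-onset track so the two
    impulse trains are never colinear.  Impulses rounding to the same
    sample are summed.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be > 0")
    n = _n_samples(events, fs)
    word = np.zeros(n)
    phon = np.zeros(n)
    for t, initial in zip(events.onset_s, events.word_initial):
        i = min(sample_index(float(t), fs), n - 1)
        if initial:
            word[i] += 1.0
        else:
            phon[i] += 1.0
    return (
        PredictorTrack("word_onset", fs, word, "impulse"),
        PredictorTrack("phoneme_onset", fs, phon, "impulse"),
    )


def feature_track(
    events: EventTable,
    values: np.ndarray,
    fs: float,
    name: str = "feature",
) -> PredictorTrack:
    """Impulse track with per-event magnitudes at phoneme onsets."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(events):
        raise ValueError(
            f"{len(values)} feature values for {len(events)} events"
        )
    n = _n_samples(events, fs)
    out = np.zeros(n)
    for t, v in zip(events.onset_s, values):
        out[min(sample_index(float(t), fs), n - 1)] += v
    return PredictorTrack(name, fs, out, "impulse")


def sublexical_features(
    events: EventTable,
    model: NGramModel,
    base: float = math.e,
    cross_word_boundaries: bool = True,
) -> FeatureSequence:
    """Phoneme surprisal and next-phoneme entropy from an n-gram model.

    Surprisal of event ``k`` conditions on the previous ``order-1``
    phonemes heard; the entropy value at event ``k`` is the entropy of the
    model's prediction for the *following* phoneme, i.e. it conditions on
    the context ending at ``k``.  With ``cross_word_boundaries=False`` the
    context is truncated at the current word's onset.
    """
    phonemes = events.phoneme_sequence()
    vocab = set(model.vocabulary)
    unseen = sorted(set(phonemes) - vocab)
    if unseen:
        raise VocabularyError(f"phonemes not in model vocabulary: {unseen}")
    m = model.order - 1
    word_start = 0
    surp = np.empty(len(phonemes))
    ent = np.empty(len(phonemes))
    for k, ph in enumerate(phonemes):
        if events.word_initial[k]:
            word_start = k
        lo = max(0, k - m) if cross_word_boundaries else max(word_start, k - m)
        ctx = phonemes[lo:k]
        surp[k] = _surprisal(model.prob(ph, ctx), base)
        lo2 = max(0, k + 1 - m) if cross_word_boundaries else max(word_start, k + 1 - m)
        ent[k] = _entropy(model.dist(phonemes[lo2 : k + 1]), base)
    return FeatureSequence(surp, ent, None, base=base)
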