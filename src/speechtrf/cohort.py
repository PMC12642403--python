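"""Incremental cohort model of spoken-word recognition.

At each word onset a prior over all lexicon words is laid out (frequency-
proportional for the lexical context model; 5-gram sentence-model
probabilities for the sentence context model).  Each subsequent phoneme
prunes candidates whose transcription is inconsistent with the prefix
heard so far and renormalizes the survivors.  Three per-phoneme features
fall out of the update: the phoneme's probability (total candidate mass
consistent with it), the entropy of the predicted next-phoneme
distribution, and the entropy over surviving candidate words.

If a phoneme eliminates every candidate (noisy alignments, out-of-lexicon
material) the state drops to a uniform fallback over the phoneme
inventory for the rest of the word: surprisal and phoneme entropy take
their uniform values, cohort entropy is 0, and the event is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import FeatureSequence
from .info import entropy as _entropy
from .info import surprisal as _surprisal
from .lexicon import EventTable, Lexicon
from .ngram import NGramModel

__all__ = ["CohortState", "cohort_init", "cohort_update", "cohort_features"]


@dataclass
class CohortState:
    """Candidate words with posterior probabilities after a consumed prefix."""

    words: tuple[str, ...]
    transcriptions: tuple[tuple[str, ...], ...]
    probs: np.ndarray
    n_consumed: int
    inventory: tuple[str, ...]
    fallback: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not self.fallback and self.probs.size:
            total = float(self.probs.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cohort probabilities sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.words)

    def next_phoneme_dist(self) -> np.ndarray:
        """Distribution over the inventory for the next phoneme.

        Mass on candidates that have already completed cannot continue and
        is excluded; the continuing mass is renormalized.  In fallback the
        distribution is uniform; with no continuing candidates it is zero.
        """
        n_inv = len(self.inventory)
        if self.fallback:
            return np.full(n_inv, 1.0 / n_inv)
        out = np.zeros(n_inv)
        index = {ph: i for i, ph in enumerate(self.inventory)}
        for trans, p in zip(self.transcriptions, self.probs):
            if len(trans) > self.n_consumed:
                out[index[trans[self.n_consumed]]] += p
        total = out.sum()
        if total > 0:
            out /= total
        return out

    def cohort_entropy(self, base: float = math.e) -> float:
        """Entropy over the candidate-word distribution (0 in fallback)."""
        if self.fallback or self.probs.size == 0:
            return 0.0
        return _entropy(self.probs, base)


def cohort_init(lexicon: Lexicon, prior: np.ndarray | None = None) -> CohortState:
    """Fresh cohort over all lexicon words with a normalized prior.

    ``prior`` aligns with ``lexicon.words``; ``None`` means the
    frequency-proportional prior.
    """
    if prior is None:
        p = lexicon.frequency_prior()
    else:
        p = np.asarray(prior, dtype=float)
        if p.shape != (len(lexicon),):
            raise ValueError("prior length must match the lexicon")
        if np.any(p < 0):
            raise ValueError("prior must be nonnegative")
        total = p.sum()
        if total <= 0:
            raise ValueError("prior must not be all zero")
        p = p / total
    return CohortState(
        words=lexicon.words,
        transcriptions=tuple(t for _, t, _ in lexicon.entries),
        probs=p,
        n_consumed=0,
        inventory=lexicon.inventory,
    )


def cohort_update(state: CohortState, phoneme: str) -> tuple[CohortState, float]:
    """Consume one phoneme; return the pruned state and the phoneme's probability.

    The phoneme probability is the total mass of candidates whose next
    phoneme matches (equivalently 1 minus the eliminated mass, counting
    already-complete candidates as eliminated).  Surviving candidates are
    renormalized.  An eliminating phoneme switches the state to the
    uniform fallback.
    """
    if len(state) == 0 and not state.fallback:
        raise ValueError("cannot update an empty cohort")
    k = state.n_consumed
    if state.fallback:
        p_uniform = 1.0 / len(state.inventory)
        new = CohortState(
            state.words, state.transcriptions, state.probs, k + 1,
            state.inventory, fallback=True,
        )
        return new, p_uniform
    keep = [
        i
        for i, t in enumerate(state.transcriptions)
        if len(t) > k and t[k] == phoneme
    ]
    p_phoneme = float(state.probs[keep].sum()) if keep else 0.0
    if not keep or p_phoneme <= 0.0:
        fallback = CohortState(
            (), (), np.empty(0), k + 1, state.inventory, fallback=True
        )
        return fallback, 1.0 / len(state.inventory)
    probs = state.probs[keep] / p_phoneme
    new = CohortState(
        words=tuple(state.words[i] for i in keep),
        transcriptions=tuple(state.transcriptions[i] for i in keep),
        probs=probs,
        n_consumed=k + 1,
        inventory=state.inventory,
    )
    return new, p_phoneme


def _sentence_prior(
    lexicon: Lexicon, context_words: list[str], word_lm: NGramModel
) -> np.ndarray:
    p = np.array([word_lm.prob(w, context_words) for w in lexicon.words])
    total = p.sum()
    if total <= 0:
        raise ValueError("sentence model assigns zero mass to the whole lexicon")
    return p / total


def cohort_features(
    events: EventTable,
    lexicon: Lexicon,
    prior_mode: str = "frequency",
    word_lm: NGramModel | None = None,
    base: float = math.e,
) -> FeatureSequence:
    """Lexical- or sentence-context features for every phoneme event.

    ``prior_mode='frequency'`` seeds each word's cohort with the
    frequency-proportional prior (lexical context model);
    ``'sentence-lm'`` seeds it with word probabilities from ``word_lm``
    conditioned on the preceding word tokens (sentence context model).
    Returns surprisal, next-phoneme entropy, and cohort (word) entropy per
    event; entropies describe the state *after* consuming the event's
    phoneme.
    """
    if prior_mode not in ("frequency", "sentence-lm"):
        raise ValueError(f"unknown prior mode {prior_mode!r}")
    if prior_mode == "sentence-lm" and word_lm is None:
        raise ValueError("sentence-lm prior requires a word n-gram model")
    known = set(lexicon.words)
    missing = sorted({w for w in events.word if w not in known})
    if missing:
        raise KeyError(f"words missing from lexicon: {missing}")

    n = len(events)
    surp = np.empty(n)
    ph_ent = np.empty(n)
    co_ent = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    state: CohortState | None = None
    preceding: list[str] = []
    n_ctx = (word_lm.order - 1) if word_lm is not None else 0
    for k in range(n):
        if events.word_initial[k]:
            if prior_mode == "frequency":
                state = cohort_init(lexicon)
            else:
                assert word_lm is not None
                prior = _sentence_prior(lexicon, preceding[-n_ctx:], word_lm)
                state = cohort_init(lexicon, prior)
            preceding.append(events.word[k])
        assert state is not None
        state, p = cohort_update(state, events.phoneme[k])
        surp[k] = _surprisal(p, base)
        ph_ent[k] = _entropy(state.next_phoneme_dist(), base)
        co_ent[k] = state.cohort_entropy(base)
        flags[k] = state.fallback
    return FeatureSequence(surp, ph_ent, co_ent, base=base, fallback=flags)
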