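"""Pronunciation lexicon and time-aligned event tables.

The lexicon maps word labels to phoneme transcriptions and corpus
frequencies and carries the phoneme inventory over which next-phoneme
distributions are defined.  Event tables hold the forced-alignment-style
timeline of (onset, word, phoneme) triples that every predictor track is
built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Lexicon", "EventTable"]


@dataclass(frozen=True)
class Lexicon:
    """Word → (phoneme transcription, frequency count) with a phoneme inventory.

    Parameters
    ----------
    entries:
        Sequence of ``(word, phonemes, frequency)`` where ``phonemes`` is a
        sequence of phoneme symbols and ``frequency`` a nonnegative count.
    inventory:
        Ordered phoneme inventory.  If omitted it is inferred from the
        transcriptions (sorted order).
    """

    entries: tuple[tuple[str, tuple[str, ...], float], ...]
    inventory: tuple[str, ...]

    def __init__(
        self,
        entries: Iterable[tuple[str, Sequence[str], float]],
        inventory: Sequence[str] | None = None,
    ) -> None:
        norm = tuple((str(w), tuple(p), float(f)) for w, p, f in entries)
        if not norm:
            raise ValueError("lexicon must contain at least one entry")
        words = [w for w, _, _ in norm]
        if len(set(words)) != len(words):
            dupes = sorted({w for w in words if words.count(w) > 1})
            raise ValueError(f"duplicate word labels in lexicon: {dupes}")
        if any(f < 0 for _, _, f in norm):
            raise ValueError("frequencies must be >= 0")
        if not any(f > 0 for _, _, f in norm):
            raise ValueError("at least one entry must have frequency > 0")
        used = {ph for _, p, _ in norm for ph in p}
        if inventory is None:
            inv = tuple(sorted(used))
        else:
            inv = tuple(inventory)
            missing = used - set(inv)
            if missing:
                raise ValueError(
                    f"transcription phonemes not in inventory: {sorted(missing)}"
                )
        object.__setattr__(self, "entries", norm)
        object.__setattr__(self, "inventory", inv)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(w for w, _, _ in self.entries)

    def transcription(self, word: str) -> tuple[str, ...]:
        for w, p, _ in self.entries:
            if w == word:
                return p
        raise KeyError(f"word not in lexicon: {word!r}")

    def frequency(self, word: str) -> float:
        for w, _, f in self.entries:
            if w == word:
                return f
        raise KeyError(f"word not in lexicon: {word!r}")

    def frequency_prior(self) -> np.ndarray:
        """Frequency-proportional prior over ``self.words`` (sums to 1)."""
        f = np.array([freq for _, _, freq in self.entries], dtype=float)
        return f / f.sum()


@dataclass
class EventTable:
    """Time-aligned word/phoneme events.

    Rows are (onset seconds, word label, phoneme symbol, word-initial flag);
    onsets are strictly increasing and lie inside ``[0, duration)``.  The
    first phoneme of every word must be flagged word-initial.
    """

    onset_s: np.ndarray
    word: list[str]
    phoneme: list[str]
    word_initial: np.ndarray
    duration: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.word_initial = np.asarray(self.word_initial, dtype=bool)
        n = len(self.onset_s)
        if not (len(self.word) == len(self.phoneme) == len(self.word_initial) == n):
            raise ValueError("event table columns must have equal length")
        if n:
            if np.any(np.diff(self.onset_s) <= 0):
                raise ValueError("event onsets must be strictly increasing")
            if self.duration <= self.onset_s[-1]:
                raise ValueError("all onsets must lie before the total duration")
            if not self.word_initial[0]:
                raise ValueError("first event must be word-initial")
            for i in range(1, n):
                if self.word[i] != self.word[i - 1] and not self.word_initial[i]:
                    raise ValueError(
                        f"word change at row {i} without word-initial flag"
                    )
        elif self.duration < 0:
            raise ValueError("duration must be >= 0")

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def n_words(self) -> int:
        return int(self.word_initial.sum())

    def phoneme_sequence(self) -> list[str]:
        return list(self.phoneme)

    def word_sequence(self) -> list[str]:
        return [w for w, init in zip(self.word, self.word_initial) if init]
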