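"""Backoff n-gram models with interpolated absolute discounting.

Fixed-order conditional token models ``p(token | previous order-1 tokens)``
used both for the 5-gram phoneme (sublexical) model and the 5-gram word
(sentence-context) model.  Smoothing is interpolated absolute discounting:

    p_n(w | c) = max(count(c,w) - d, 0) / count(c)
                 + d * D(c) / count(c) * p_{n-1}(w | c[1:])

where ``D(c)`` is the number of distinct continuations of context ``c`` and
the base case is the uniform distribution over the vocabulary.  With
``d = 0`` and a seen context this reduces exactly to maximum-likelihood
count ratios.  Models are stored in standard backoff form (per-n-gram log10
probabilities plus per-context backoff weights), which is also what the
ARPA file format serializes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["NGramModel", "train_ngram", "VocabularyError"]


class VocabularyError(KeyError):
    """A queried token is outside the model's vocabulary."""


_LOG_PLACEHOLDER = -99.0  # ARPA convention for context-only entries


@dataclass
class NGramModel:
    """Backoff-smoothed fixed-order n-gram model.

    ``logp`` maps n-gram tuples (any order 1..N) to log10 conditional
    probabilities; ``backoff`` maps seen context tuples to linear backoff
    weights.  Contexts absent from ``backoff`` back off with weight 1.
    """

    order: int
    vocabulary: tuple[str, ...]
    logp: dict[tuple[str, ...], float]
    backoff: dict[tuple[str, ...], float]
    discount: float = 0.0
    pad_symbol: str | None = None
    unk_symbol: str | None = None
    _vocab_set: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._vocab_set = frozenset(self.vocabulary)

    # -- queries ---------------------------------------------------------
    def _resolve(self, token: str) -> str:
        if token in self._vocab_set:
            return token
        if self.unk_symbol is not None:
            return self.unk_symbol
        raise VocabularyError(f"token {token!r} not in model vocabulary")

    def _p(self, token: str, context: tuple[str, ...]) -> float:
        key = context + (token,)
        lp = self.logp.get(key)
        if lp is not None and lp > _LOG_PLACEHOLDER:
            return 10.0 ** lp
        if not context:
            # token in vocabulary but unlisted at unigram level: only possible
            # for read-in ARPA models without an explicit entry
            return 0.0
        w = self.backoff.get(context, 1.0)
        return w * self._p(token, context[1:])

    def prob(self, token: str, context: Sequence[str] = ()) -> float:
        """Conditional probability of ``token`` given trailing ``context``."""
        tok = self._resolve(token)
        ctx = []
        for c in context:
            if c in self._vocab_set or c == self.pad_symbol:
                ctx.append(c)
            elif self.unk_symbol is not None:
                ctx.append(self.unk_symbol)
            else:
                ctx.append(c)  # unseen context token; backoff path handles it
        if self.pad_symbol is not None and len(ctx) < self.order - 1:
            ctx = [self.pad_symbol] * (self.order - 1 - len(ctx)) + ctx
        ctx_t = tuple(ctx[max(0, len(ctx) - (self.order - 1)):])
        return self._p(tok, ctx_t)

    def dist(self, context: Sequence[str] = ()) -> np.ndarray:
        """Full conditional distribution over ``self.vocabulary``."""
        return np.array([self.prob(w, context) for w in self.vocabulary])


def _count_ngrams(
    sequences: list[list[str]], order: int, pad_symbol: str | None
) -> list[dict]:
    """Per-order n-gram counts; only windows ending in a real token count."""
    counts: list[dict] = [dict() for _ in range(order + 1)]  # index by n
    for seq in sequences:
        if pad_symbol is not None:
            padded = [pad_symbol] * (order - 1) + seq
            first_real = order - 1
        else:
            padded = seq
            first_real = 0
        for n in range(1, order + 1):
            table = counts[n]
            for end in range(first_real, len(padded)):
                j = end - n + 1
                if j < 0:
                    continue
                gram = tuple(padded[j : end + 1])
                table[gram] = table.get(gram, 0) + 1
    return counts


def train_ngram(
    corpus: Iterable[Sequence[str]] | Sequence[str],
    order: int,
    discount: float = 0.0,
    pad_symbol: str | None = None,
    unk_symbol: str | None = None,
    extra_vocabulary: Sequence[str] = (),
) -> NGramModel:
    """Train an interpolated absolute-discount model of the given order.

    ``corpus`` is one token sequence or an iterable of sequences.  With
    ``discount=0`` the conditionals for seen contexts equal ML count
    ratios.  ``pad_symbol`` (if given) left-pads every sequence so that
    utterance-initial contexts are defined; it never appears as a predicted
    token.  ``unk_symbol`` (if given) joins the vocabulary so out-of-
    vocabulary queries receive its smoothed probability.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 <= discount < 1.0:
        raise ValueError("discount must lie in [0, 1)")
    items = list(corpus)
    if items and all(isinstance(t, str) for t in items):
        seqs = [items]  # a single token sequence
    else:
        seqs = [list(s) for s in items]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("corpus must be non-empty")
    longest = max(len(s) for s in seqs)
    if order > longest + 1:
        raise ValueError(
            f"order {order} exceeds longest sequence length {longest} + 1"
        )

    vocab = sorted({t for s in seqs for t in s} | set(extra_vocabulary))
    if unk_symbol is not None and unk_symbol not in vocab:
        vocab.append(unk_symbol)
    vocab_t = tuple(vocab)
    V = len(vocab_t)

    counts = _count_ngrams(seqs, order, pad_symbol)
    logp: dict[tuple[str, ...], float] = {}
    backoff: dict[tuple[str, ...], float] = {}

    # context totals and distinct-continuation counts per order
    ctx_total: list[dict] = [dict() for _ in range(order + 1)]
    ctx_types: list[dict] = [dict() for _ in range(order + 1)]
    for n in range(1, order + 1):
        for gram, c in counts[n].items():
            ctx = gram[:-1]
            ctx_total[n][ctx] = ctx_total[n].get(ctx, 0) + c
            ctx_types[n][ctx] = ctx_types[n].get(ctx, 0) + 1

    model = NGramModel(
        order=order,
        vocabulary=vocab_t,
        logp=logp,
        backoff=backoff,
        discount=discount,
        pad_symbol=pad_symbol,
        unk_symbol=unk_symbol,
    )

    # unigrams: interpolate with the uniform base distribution
    T1 = ctx_total[1][()]
    D1 = ctx_types[1][()]
    for w in vocab_t:
        c = counts[1].get((w,), 0)
        p = max(c - discount, 0.0) / T1 + discount * D1 / T1 / V
        logp[(w,)] = math.log10(p) if p > 0 else -math.inf

    # higher orders, built bottom-up so lower-level queries are complete
    for n in range(2, order + 1):
        for ctx, T in ctx_total[n].items():
            D = ctx_types[n][ctx]
            bo = discount * D / T
            backoff[ctx] = bo
        for gram, c in counts[n].items():
            ctx = gram[:-1]
            w = gram[-1]
            T = ctx_total[n][ctx]
            p = max(c - discount, 0.0) / T + backoff[ctx] * model._p(w, ctx[1:])
            logp[gram] = math.log10(p) if p > 0 else -math.inf
    return model
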