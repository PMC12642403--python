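"""Surprisal and entropy of discrete predictive distributions.

Surprisal of an observed outcome is ``-log p(outcome | context)``; entropy
is the expectation of surprisal over the predicted distribution,
``-sum_i p_i log p_i``.  The log base (2 for bits, e for nats) is a
parameter everywhere; downstream predictors are standardized before model
fitting, so the base only rescales feature tracks.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["InfiniteSurprisalError", "surprisal", "entropy", "information_measures"]

_SUM_TOL = 1e-9


class InfiniteSurprisalError(ValueError):
    """The observed outcome has probability zero under the model."""


def _log(x: float, base: float) -> float:
    return math.log(x) if base == math.e else math.log(x) / math.log(base)


def surprisal(p_observed: float, base: float = math.e) -> float:
    """``-log p`` of the observed outcome, in the chosen base."""
    if p_observed <= 0.0:
        raise InfiniteSurprisalError(
            f"observed outcome has probability {p_observed}; surprisal is infinite"
        )
    return max(0.0, -_log(p_observed, base))


def entropy(dist: np.ndarray, base: float = math.e) -> float:
    """Shannon entropy ``-sum p log p`` of a probability vector.

    Zero-probability outcomes contribute nothing (0 log 0 := 0).
    """
    p = np.asarray(dist, dtype=float)
    if np.any(p < -_SUM_TOL):
        raise ValueError("probabilities must be nonnegative")
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    h = -float(np.sum(p * np.log(p)))
    if base != math.e:
        h /= math.log(base)
    return max(0.0, h)


def information_measures(
    dist: np.ndarray, observed: int, base: float = math.e
) -> tuple[float, float]:
    """Surprisal of ``dist[observed]`` and entropy of ``dist``.

    ``dist`` must sum to 1 within 1e-9 and ``observed`` indexes the outcome
    that occurred.
    """
    p = np.asarray(dist, dtype=float)
    total = float(p.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"distribution sums to {total}, not 1")
    if not 0 <= observed < p.size:
        raise IndexError("observed outcome index out of range")
    return surprisal(float(p[observed]), base), entropy(p, base)
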