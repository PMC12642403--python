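"""Lagged Hamming-window basis for temporal response functions.

Kernels are expressed as coefficient vectors over 50 ms wide Hamming
bumps whose centers tile the lag window [-100, 1000) ms at a configurable
stride (default: one sample).  Negative lags give anticipatory kernel
samples.  The module also provides the mean-absolute standardization
applied to every predictor and response before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming

__all__ = ["TRFBasis", "make_basis", "standardize", "build_design"]


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale to unit mean absolute value.

    Returns ``(standardized, center, scale)`` with
    ``standardized = (values - center) / scale``.  Constant input has no
    scale and is rejected.
    """
    x = np.asarray(values, dtype=float)
    center = float(x.mean())
    centered = x - center
    scale = float(np.abs(centered).mean())
    if scale <= 0.0:
        raise ValueError("cannot standardize a constant signal")
    return centered / scale, center, scale


@dataclass(frozen=True)
class TRFBasis:
    """Hamming-bump basis over a lag window.

    ``centers`` are bump-center lags in samples (may be negative);
    ``window`` is the Hamming bump; ``matrix`` maps basis coefficients to
    the lag-domain kernel sampled at ``lags`` (samples).
    """

    fs: float
    tmin_ms: float
    tmax_ms: float
    width_ms: float
    stride_ms: float
    centers: np.ndarray
    window: np.ndarray
    lags: np.ndarray
    matrix: np.ndarray

    @property
    def n_elements(self) -> int:
        return len(self.centers)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    def kernel(self, coef: np.ndarray) -> np.ndarray:
        """Lag-domain kernel(s) from basis coefficients (last axis)."""
        return np.asarray(coef) @ self.matrix.T


def make_basis(
    tmin_ms: float = -100.0,
    tmax_ms: float = 1000.0,
    width_ms: float = 50.0,
    stride_ms: float | None = None,
    fs: float = 100.0,
) -> TRFBasis:
    """Build the Hamming basis; centers tile [tmin, tmax) at the stride."""
    if tmin_ms >= tmax_ms:
        raise ValueError("tmin must be < tmax")
    if width_ms <= 0 or (stride_ms is not None and stride_ms <= 0):
        raise ValueError("width and stride must be > 0")
    if stride_ms is None:
        stride_ms = 1000.0 / fs  # one sample
    w = int(round(width_ms * fs / 1000.0))
    if w < 2:
        raise ValueError(
            f"basis width {width_ms} ms is under 2 samples at fs={fs} Hz"
        )
    centers_ms = np.arange(tmin_ms, tmax_ms - 1e-9, stride_ms)
    centers = np.unique(np.round(centers_ms * fs / 1000.0).astype(np.int64))
    window = hamming(w, sym=True)
    hw = (w - 1) // 2
    lag_min = int(centers.min()) - hw
    lag_max = int(centers.max()) + (w - 1 - hw)
    lags = np.arange(lag_min, lag_max + 1)
    matrix = np.zeros((len(lags), len(centers)))
    for j, c in enumerate(centers):
        start = c - hw - lag_min
        matrix[start : start + w, j] = window
    return TRFBasis(
        fs=fs,
        tmin_ms=tmin_ms,
        tmax_ms=tmax_ms,
        width_ms=width_ms,
        stride_ms=float(stride_ms),
        centers=centers,
        window=window,
        lags=lags,
        matrix=matrix,
    )


def build_design(x: np.ndarray, basis: TRFBasis) -> np.ndarray:
    """Design matrix of one predictor segment under the basis.

    Column ``j`` is the predictor convolved with bump ``j``; lags falling
    outside the segment are zero-padded, so segments never leak into each
    other.  Shape ``(len(x), n_elements)``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = len(basis.window)
    hw = (w - 1) // 2
    z = np.convolve(x, basis.window)  # z[t] = sum_u win[u] x[t-u]
    D = np.zeros((n, basis.n_elements))
    for j, c in enumerate(basis.centers):
        offset = int(c) - hw  # col_j[s] = z[s - offset]
        s_lo = max(0, offset)
        s_hi = min(n, offset + n + w - 1)
        if s_lo < s_hi:
            D[s_lo:s_hi, j] = z[s_lo - offset : s_hi - offset]
    return D
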