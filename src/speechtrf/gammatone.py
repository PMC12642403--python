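"""Auditory-spectrogram predictors from a gammatone filterbank.

Eight 4th-order gammatone bands with log-spaced center frequencies between
10 and 5000 Hz.  Per band the half-wave-rectified filter output is
resampled to the analysis rate to give an envelope track; the onset track
is the half-wave-rectified first difference of that envelope.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .features import PredictorTrack

__all__ = ["gammatone_center_frequencies", "gammatone_predictors"]


def gammatone_center_frequencies(
    n_bands: int = 8, fmin: float = 10.0, fmax: float = 5000.0
) -> np.ndarray:
    return np.geomspace(fmin, fmax, n_bands)


def gammatone_predictors(
    waveform: np.ndarray,
    audio_fs: float,
    fs: float = 100.0,
    n_bands: int = 8,
    fmin: float = 10.0,
    fmax: float = 5000.0,
) -> tuple[list[PredictorTrack], list[PredictorTrack]]:
    """Envelope and onset tracks per gammatone band, at the analysis rate."""
    if audio_fs < 10_000:
        raise ValueError("audio sampling rate must be >= 10 kHz")
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    # require at least one period of the lowest band's center frequency
    if len(x) < int(audio_fs / fmin):
        raise ValueError("waveform shorter than one filter length")
    up = int(round(fs))
    down = int(round(audio_fs))
    envelopes: list[PredictorTrack] = []
    onsets: list[PredictorTrack] = []
    # FIR gammatone kernels: stable at low center frequencies where the
    # IIR realization breaks down numerically at audio rates
    sos = signal.butter(4, 0.4 * fs, btype="low", fs=audio_fs, output="sos")
    for i, fc in enumerate(gammatone_center_frequencies(n_bands, fmin, fmax)):
        taps, _ = signal.gammatone(fc, "fir", fs=audio_fs)
        band = signal.fftconvolve(x, taps, mode="full")[: len(x)]
        rect = np.clip(band, 0.0, None)
        smooth = signal.sosfiltfilt(sos, rect)
        env = signal.resample_poly(smooth, up, down)
        env = np.clip(env, 0.0, None)
        onset = np.clip(np.diff(env, prepend=0.0), 0.0, None)
        envelopes.append(
            PredictorTrack(f"gammatone_env_{i}", fs, env, "continuous")
        )
        onsets.append(
            PredictorTrack(f"gammatone_onset_{i}", fs, onset, "continuous")
        )
    return envelopes, onsets
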