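"""Baseline MFCC features with cepstral mean subtraction and deltas.

The mel mapping is approximately linear below 1 kHz and logarithmic
above; 30 triangular filters span 0 to Nyquist, the 0th cepstral
coefficient is dropped and the per-file coefficient means are removed.
No pre-emphasis is applied.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct

LOG_FLOOR = 1e-30


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: int) -> np.ndarray:
    """Triangular mel-spaced filters as a (n_filters, n_fft//2+1) matrix."""
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2.0),
                          n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(frame: np.ndarray, rate: int, n_coeffs: int = 22,
         n_filters: int = 30) -> np.ndarray:
    """MFCCs 1..n_coeffs of one (already windowed) frame.

    FFT magnitude -> triangular mel filters -> log energies -> DCT-II
    (orthonormal) -> drop the gain-carrying 0th coefficient.
    """
    if n_coeffs > n_filters:
        raise ValueError("n_coeffs cannot exceed n_filters")
    x = np.asarray(frame, dtype=np.float64)
    if not np.any(x):
        raise ValueError("all-zero frame has no cepstrum")
    n_fft = int(2 ** np.ceil(np.log2(len(x))))
    mag = np.abs(np.fft.rfft(x, n_fft))
    fb = mel_filterbank(n_filters, n_fft, rate)
    energies = fb @ mag
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho")
    return ceps[1:n_coeffs + 1]


def cepstral_mean_subtract(F: np.ndarray) -> np.ndarray:
    """Remove the per-coefficient time mean (rows = frames)."""
    F = np.asarray(F, dtype=np.float64)
    return F - F.mean(axis=0, keepdims=True)


def _regression_filter(F: np.ndarray, half_width: int) -> np.ndarray:
    """Standard regression delta: sum_k k*(c[t+k]-c[t-k]) / (2*sum_k k^2)."""
    n = F.shape[0]
    pad = np.concatenate([np.repeat(F[:1], half_width, axis=0), F,
                          np.repeat(F[-1:], half_width, axis=0)])
    norm = 2.0 * sum(k * k for k in range(1, half_width + 1))
    out = np.zeros_like(F)
    for k in range(1, half_width + 1):
        out += k * (pad[half_width + k:half_width + k + n]
                    - pad[half_width - k:half_width - k + n])
    return out / norm


def add_deltas(F: np.ndarray, order: int = 1,
               delta_len: int = 9, delta2_len: int = 3) -> np.ndarray:
    """Append Δ (and ΔΔ) blocks to a frame-by-feature matrix.

    Δ uses a length-``delta_len`` FIR regression filter (half-width 4 by
    default) over the static features; ΔΔ applies a length-``delta2_len``
    filter to Δ. Edges are replicated. ``order`` 0 returns F unchanged.
    """
    F = np.asarray(F, dtype=np.float64)
    if order == 0:
        return F
    if order not in (1, 2):
        raise ValueError("order must be 0, 1 or 2")
    d1 = _regression_filter(F, (delta_len - 1) // 2)
    blocks = [F, d1]
    if order == 2:
        blocks.append(_regression_filter(d1, (delta2_len - 1) // 2))
    return np.hstack(blocks)
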