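"""Audio front-end: WAV I/O, framing/windowing and pitch estimation.

Every parameterization path (modulation-spectrum morphology and the MFCC
baseline) shares this preprocessing: signals are read as mono waveforms
normalized to [-1, 1], cut into Hamming-tapered frames with 50% overlap,
and each frame gets an autocorrelation pitch estimate that downstream
features normalize by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly


@dataclass
class Waveform:
    """A mono audio signal with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class FrameSeries:
    """Windowed analysis frames plus enough bookkeeping to undo the taper."""

    frames: np.ndarray            # (n_frames, frame_len), taper applied
    sample_rate: int
    frame_len_ms: float
    overlap_fraction: float
    window: np.ndarray            # the taper (all ones for rectangular)
    starts: np.ndarray            # start sample of each frame

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]

    @property
    def hop(self) -> int:
        return int(round(self.frame_len * (1.0 - self.overlap_fraction)))

    def raw_frames(self) -> np.ndarray:
        """Frames with the taper divided out (exact signal slices)."""
        w = np.where(self.window == 0.0, 1.0, self.window)
        return self.frames / w


@dataclass
class PitchTrack:
    f0: np.ndarray                # Hz per frame; NaN where unvoiced
    voiced: np.ndarray            # bool per frame

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)

    def median_f0(self) -> float:
        if not self.voiced.any():
            return float("nan")
        return float(np.median(self.f0[self.voiced]))


_PCM_SCALES = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31,
               np.dtype(np.uint8): 2 ** 7}


def read_audio(path, resample_to: int | None = None) -> Waveform:
    """Read a WAV file into a normalized mono :class:`Waveform`.

    Integer PCM is scaled to [-1, 1]; stereo is averaged to mono with a
    warning; ``resample_to`` triggers polyphase resampling.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise IOError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"WAV file {path!r} contains no samples")
    if data.ndim == 2:
        warnings.warn(f"{path!r} is multichannel; averaging to mono")
        data = data.astype(np.float64).mean(axis=1)
    if data.dtype in _PCM_SCALES:
        scale = _PCM_SCALES[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            data = (data.astype(np.float64) - 128.0) / scale
        else:
            data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    w = Waveform(data, int(rate))
    if resample_to is not None and resample_to != w.sample_rate:
        w = resample(w, int(resample_to))
    return w


def write_audio(path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * (2 ** 15 - 1)).astype(np.int16)
    wavfile.write(path, int(w.sample_rate), pcm)


def resample(w: Waveform, new_rate: int) -> Waveform:
    from math import gcd

    g = gcd(new_rate, w.sample_rate)
    out = resample_poly(w.samples, new_rate // g, w.sample_rate // g)
    return Waveform(out, new_rate)


def frame_signal(w: Waveform, frame_len_ms: float,
                 overlap_fraction: float = 0.5,
                 window: str | None = "hamming") -> FrameSeries:
    """Cut a waveform into tapered frames.

    ``n_frames = floor((N - L) / H) + 1`` with hop ``H = L*(1-overlap)``;
    a tail shorter than one frame is dropped so every frame is fully
    contained in the signal.
    """
    L = int(round(frame_len_ms * w.sample_rate / 1000.0))
    if L < 2:
        raise ValueError("frame length must span at least 2 samples")
    N = len(w.samples)
    if N < L:
        raise ValueError(
            f"signal of {N} samples is shorter than one {L}-sample frame")
    H = int(round(L * (1.0 - overlap_fraction)))
    if H < 1:
        raise ValueError("overlap_fraction leaves an empty hop")
    n_frames = (N - L) // H + 1
    starts = np.arange(n_frames) * H
    idx = starts[:, None] + np.arange(L)[None, :]
    frames = w.samples[idx]
    if window is None or window == "rectangular":
        taper = np.ones(L)
    else:
        taper = get_window(window, L, fftbins=False)
    return FrameSeries(frames * taper, w.sample_rate, frame_len_ms,
                       overlap_fraction, taper, starts)


def estimate_pitch(frame: np.ndarray, rate: int,
                   f0_range: tuple[float, float] = (60.0, 500.0),
                   voicing_threshold: float = 0.3) -> tuple[float, bool]:
    """Normalized-autocorrelation pitch estimate with parabolic refinement.

    Returns ``(f0_hz, voiced)``; ``voiced`` is False when the best in-range
    autocorrelation peak falls below ``voicing_threshold`` (the estimate is
    then NaN). Scale-invariant: k*x gives the same result for k > 0.
    """
    x = np.asarray(frame, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    e0 = float(np.dot(x, x))
    if e0 <= 0.0:
        return float("nan"), False
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    r = r / r[0]
    lag_min = max(2, int(np.floor(rate / f0_range[1])))
    lag_max = min(n - 2, int(np.ceil(rate / f0_range[0])))
    if lag_max <= lag_min:
        return float("nan"), False
    seg = r[lag_min:lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    peak = r[k]
    if peak < voicing_threshold:
        return float("nan"), False
    # parabolic interpolation around the integer-lag peak
    y0, y1, y2 = r[k - 1], r[k], r[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    f0 = rate / (k + delta)
    f0 = float(np.clip(f0, f0_range[0], f0_range[1]))
    return f0, True


def track_pitch(fs: FrameSeries,
                f0_range: tuple[float, float] = (60.0, 500.0)) -> PitchTrack:
    """Per-frame pitch over a frame series (taper removed before analysis)."""
    raw = fs.raw_frames()
    f0 = np.empty(fs.n_frames)
    voiced = np.empty(fs.n_frames, dtype=bool)
    for i in range(fs.n_frames):
        f0[i], voiced[i] = estimate_pitch(raw[i], fs.sample_rate, f0_range)
    return PitchTrack(f0, voiced)
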