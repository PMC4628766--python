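"""Per-file feature extraction driving either parameterization path.

A file becomes a (n_frames, n_features) matrix: Hamming frames with 50%
overlap, a per-frame autocorrelation pitch gate (unvoiced frames are
dropped because the pitch-normalized parameters are undefined without a
pitch), then either the morphological parameters of the modulation
spectrum or MFCCs with cepstral mean subtraction, optionally followed
by Δ / Δ+ΔΔ regression dynamics.
"""

from __future__ import annotations

import logging

import numpy as np

from .audio import Waveform, frame_signal, track_pitch
from .config import ExperimentConfig
from .mfcc import add_deltas, cepstral_mean_subtract, mfcc
from .morphology import MorphConfig, extract_features, feature_names

log = logging.getLogger(__name__)

RMS_GATE_DB = -40.0   # frames this far below the file RMS are discarded


def file_features(w: Waveform, cfg: ExperimentConfig) -> np.ndarray:
    """Feature matrix (frames x features) for one waveform."""
    fs = frame_signal(w, cfg.frame_ms, cfg.overlap_fraction, "hamming")
    raw = fs.raw_frames()

    file_rms = np.sqrt(np.mean(w.samples ** 2))
    frame_rms = np.sqrt(np.mean(raw ** 2, axis=1))
    loud = frame_rms > file_rms * 10.0 ** (RMS_GATE_DB / 20.0)

    if cfg.features == "mfcc":
        rows = [mfcc(fs.frames[i], fs.sample_rate,
                     cfg.n_coeffs, cfg.n_filters)
                for i in range(fs.n_frames) if loud[i]]
        if not rows:
            raise ValueError("no frames above the energy gate")
        F = cepstral_mean_subtract(np.vstack(rows))
    else:
        track = track_pitch(fs, (cfg.f0_min, cfg.f0_max))
        keep = track.voiced & loud
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("dropping %d unvoiced/quiet frames of %d",
                     n_dropped, fs.n_frames)
        if not keep.any():
            raise ValueError("no voiced frames: cannot extract "
                             "pitch-normalized features")
        mcfg = MorphConfig(frame_ms=cfg.frame_ms, nb=cfg.nb,
                           envelope_mode=cfg.envelope_mode,
                           max_mod_freq=cfg.max_mod_freq,
                           n_acoustic_bands=cfg.n_acoustic_bands)
        F = np.vstack([
            extract_features(fs.frames[i], fs.sample_rate, track.f0[i], mcfg)
            for i in range(fs.n_frames) if keep[i]])
    return add_deltas(F, cfg.deltas)


def feature_labels(cfg: ExperimentConfig) -> list[str]:
    if cfg.features == "mfcc":
        base = [f"mfcc_{i + 1}" for i in range(cfg.n_coeffs)]
    else:
        base = feature_names(cfg.nb)
    names = list(base)
    if cfg.deltas >= 1:
        names += [f"d_{n}" for n in base]
    if cfg.deltas == 2:
        names += [f"dd_{n}" for n in base]
    return names


def corpus_features(waveforms, cfg: ExperimentConfig) -> list[np.ndarray]:
    """Feature matrices for a list of waveforms (one matrix per file)."""
    return [file_features(w, cfg) for w in waveforms]
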