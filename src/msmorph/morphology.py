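"""Morphological parameters of the modulation spectrum.

Eight parameter families summarize the shape of a frame's modulation
spectrum E(fa, fm):

MSC
    Per-modulation-band acoustic centroid, normalized by the pitch
    frequency: ``MSC(b) = sum_a fa*E(a,b) / (f_pitch * sum_a E(a,b))``
    with E the band-reduced modulus energy. Values near 1 mean the
    energy of that modulation band sits around the pitch partial.
DRB
    Dynamic range per reduced modulation band, dB: the ratio between the
    largest and smallest band energy along the acoustic axis. Measures
    the flatness of the spectrum at each modulation frequency.
LMR
    Low Modulation Ratio, dB: in the acoustic band containing the pitch,
    the ratio of the first modulation band's energy to the cumulative
    energy of all modulation bands up to and including the one holding
    25 Hz. 0 dB means no sub-25 Hz side bands (no tremor); always <= 0.
MSH
    Homogeneity: mean squared deviation of each point from its 3x3
    neighborhood mean (borders use the truncated valid neighborhood).
    Computed on the modulus image and on the unwrapped phase.
MSW
    Contrast, a Weber-fraction sum over the 4-neighbor graph:
    ``|M - M'| / (M + M')`` summed over vertical/horizontal neighbors of
    each point, averaged over points. Modulus-image and phase variants.

The modulus "image" fed to MSH/MSW is the dB modulus limited to a fixed
display dynamic range (40 dB below the frame maximum, shifted so the
floor is 0): texture measures on the raw linear modulus are dominated
by numerically tiny floor cells whose relative fluctuations carry no
voice information, whereas the range-limited dB image behaves like the
rendered spectrogram the measures are meant to mimic — flat floor
regions contribute zero contrast, and perturbation energy rising above
the floor adds texture. A side effect is that both modulus texture
parameters are invariant to global amplitude scaling.
CIL
    Cumulative Intersection Level, dB: the level at which the ascending
    and descending cumulative histograms of the modulus (in dB) cross —
    a robust central level of the spectrum.
PALA / RALA
    Fraction / odds of points whose modulus is at or above the linear
    modulus mean. Dysphonic voices disperse energy away from the 0 Hz
    column, raising both. They are linked by the exact identity
    ``RALA = PALA / (1 - PALA)``.

The per-frame feature vector concatenates
``[MSC(nb), DRB(nb), LMR, MSW_mod, MSW_phase, MSH_mod, MSH_phase, CIL,
PALA, RALA]`` — ``2*nb + 8`` values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .modspec import ModSpec, ReducedModSpec, compute_modspec, \
    reduce_mod_bands, unwrap_phase

log = logging.getLogger(__name__)

TREMOR_BAND_HZ = 25.0   # upper edge of the low-modulation (tremor) range
TEXTURE_RANGE_DB = 40.0  # display dynamic range of the texture image


@dataclass
class MorphConfig:
    """Configuration of the modulation-spectrum feature path."""

    frame_ms: float = 140.0
    nb: int = 22                      # reduced modulation bands (4..26)
    envelope_mode: str = "hilbert"
    max_mod_freq: float = 240.0
    n_acoustic_bands: int = 128


def msc(r: ReducedModSpec, f_pitch: float) -> np.ndarray:
    """Acoustic centroid per reduced modulation band, in pitch units."""
    if f_pitch <= 0:
        raise ValueError("f_pitch must be positive")
    num = (r.fa[:, None] * r.band_energy).sum(axis=0)
    den = r.band_energy.sum(axis=0)
    out = np.zeros(r.nb)
    ok = den > 0
    if not ok.all():
        log.warning("msc: %d zero-energy modulation bands imputed as 0",
                    int((~ok).sum()))
    out[ok] = num[ok] / (f_pitch * den[ok])
    return out


def drb(r: ReducedModSpec, floor_rel: float = 1e-12) -> np.ndarray:
    """Dynamic range (dB) of each reduced modulation band."""
    e = r.band_energy
    floor = floor_rel * max(e.max(), np.finfo(float).tiny)
    e = np.maximum(e, floor)
    return 10.0 * np.log10(e.max(axis=0) / e.min(axis=0))


def lmr(ms: ModSpec, f_pitch: float) -> float:
    """Low Modulation Ratio (dB, <= 0) in the pitch acoustic band."""
    a = ms.acoustic_band_of(f_pitch)
    m25 = ms.mod_band_of(TREMOR_BAND_HZ)
    if ms.fm[-1] < TREMOR_BAND_HZ:
        raise ValueError("modulation grid does not reach 25 Hz")
    power = np.abs(ms.E[a, :m25 + 1]) ** 2
    den = power.sum()
    if den <= 0:
        raise ValueError("degenerate all-zero pitch band in LMR")
    return float(10.0 * np.log10(power[0] / den))


def msh(M: np.ndarray) -> float:
    """Homogeneity: mean squared deviation from the local 3x3 mean."""
    M = np.asarray(M, dtype=np.float64)
    if M.shape[0] < 3 or M.shape[1] < 3:
        raise ValueError("matrix must be at least 3x3")
    kernel = np.ones((3, 3))
    local_sum = convolve2d(M, kernel, mode="same")
    counts = convolve2d(np.ones_like(M), kernel, mode="same")
    local_mean = local_sum / counts
    return float(np.mean((M - local_mean) ** 2))


def msw(M: np.ndarray) -> float:
    """Contrast: mean over points of the 4-neighbor Weber-fraction sum.

    Terms with a zero-magnitude denominator (both neighbors zero, or a
    cancelling phase pair) contribute 0.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("matrix must be at least 2x2")
    total = np.zeros_like(M)
    for shift_axis in (0, 1):
        d = np.abs(np.diff(M, axis=shift_axis))
        s = np.abs(M[:-1, :] + M[1:, :]) if shift_axis == 0 else \
            np.abs(M[:, :-1] + M[:, 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(s > 0, d / np.where(s > 0, s, 1.0), 0.0)
        if shift_axis == 0:
            total[:-1, :] += term
            total[1:, :] += term
        else:
            total[:, :-1] += term
            total[:, 1:] += term
    return float(total.mean())


def cil(ms_or_modulus, bin_width_db: float = 1.0,
        floor_rel: float = 1e-12) -> float:
    """Cumulative Intersection Level (dB) of the modulus histogram.

    The modulus is floored at ``floor_rel * max`` and converted to dB
    (20*log10). Ascending/descending cumulative counts are evaluated on
    a ``bin_width_db`` grid anchored at the minimum level, and their
    crossing is located by linear interpolation (the midpoint of the
    flat region when they are equal over a range).
    """
    if isinstance(ms_or_modulus, ModSpec):
        mag = ms_or_modulus.modulus()
    else:
        mag = np.asarray(ms_or_modulus, dtype=np.float64)
    mag = mag.ravel()
    floor = floor_rel * max(mag.max(), np.finfo(float).tiny)
    levels = 20.0 * np.log10(np.maximum(mag, floor))
    lo, hi = levels.min(), levels.max()
    if hi - lo < 1e-12:
        return float(lo)
    grid = lo + np.arange(0.0, hi - lo + bin_width_db, bin_width_db)
    srt = np.sort(levels)
    up = np.searchsorted(srt, grid, side="right").astype(float)
    down = (len(srt) - np.searchsorted(srt, grid, side="left")).astype(float)
    g = up - down                          # non-decreasing in the level
    if g[0] >= 0:
        return float(grid[0]) if g[0] == 0 else float(lo)
    k = int(np.searchsorted(g >= 0, True))   # first grid point with g >= 0
    if g[k] == 0:
        last = k
        while last + 1 < len(g) and g[last + 1] == 0:
            last += 1
        return float(0.5 * (grid[k] + grid[last]))
    x0, x1 = grid[k - 1], grid[k]
    y0, y1 = g[k - 1], g[k]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def pala_rala(ms_or_modulus) -> tuple[float, float]:
    """Fraction (PALA) and odds (RALA) of points at/above the modulus mean."""
    if isinstance(ms_or_modulus, ModSpec):
        mag = ms_or_modulus.modulus()
    else:
        mag = np.asarray(ms_or_modulus, dtype=np.float64)
    mag = mag.ravel()
    n_total = mag.size
    n_above = int((mag >= mag.mean()).sum())
    n_below = n_total - n_above
    if n_below == 0:
        raise ValueError("degenerate modulation spectrum: no points "
                         "below the modulus mean")
    pala = n_above / n_total
    return pala, n_above / n_below


def rala_from_pala(pala: float) -> float:
    """The exact identity RALA = PALA / (1 - PALA)."""
    if not 0.0 <= pala < 1.0:
        raise ValueError("PALA must lie in [0, 1)")
    return pala / (1.0 - pala)


def texture_image(modulus: np.ndarray,
                  range_db: float = TEXTURE_RANGE_DB) -> np.ndarray:
    """dB modulus limited to ``range_db`` below the maximum, floor at 0."""
    mag = np.asarray(modulus, dtype=np.float64)
    peak = max(mag.max(), np.finfo(float).tiny)
    img = 20.0 * np.log10(np.maximum(mag, peak * 10.0 ** (-range_db / 20.0)))
    return img - img.min()


def feature_names(nb: int) -> list[str]:
    return ([f"msc_{b + 1}" for b in range(nb)]
            + [f"drb_{b + 1}" for b in range(nb)]
            + ["lmr", "msw_mod", "msw_phase", "msh_mod", "msh_phase",
               "cil", "pala", "rala"])


def extract_features(frame: np.ndarray, rate: int, f_pitch: float,
                     config: MorphConfig | None = None) -> np.ndarray:
    """Full morphological feature vector (length 2*nb + 8) for one frame."""
    cfg = config or MorphConfig()
    ms = compute_modspec(frame, rate,
                         n_acoustic_bands=cfg.n_acoustic_bands,
                         max_mod_freq=cfg.max_mod_freq,
                         envelope_mode=cfg.envelope_mode)
    reduced = reduce_mod_bands(ms, cfg.nb)
    modulus = ms.modulus()
    image = texture_image(modulus)
    phase = unwrap_phase(ms)
    p, r = pala_rala(modulus)
    vec = np.concatenate([
        msc(reduced, f_pitch),
        drb(reduced),
        [lmr(ms, f_pitch),
         msw(image), msw(phase),
         msh(image), msh(phase),
         cil(modulus), p, r],
    ])
    return vec
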