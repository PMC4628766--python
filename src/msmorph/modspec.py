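"""Modulation spectrum of an analysis frame.

The modulation spectrum E(fa, fm) is a joint representation of how the
energy carried at acoustic frequency fa is amplitude-modulated at
modulation frequency fm. It is obtained per acoustic band by detecting
the subband envelope (Hilbert magnitude, or coherent demodulation by the
band carrier) and Fourier-analyzing that envelope. In sustained vowels,
low-frequency side bands around the pitch band reveal tremor and other
slow instabilities of phonation, while a clean phonation concentrates
each band's energy in the 0 Hz modulation bin.

Implementation notes
--------------------
* The acoustic axis is divided into ``n_acoustic_bands`` uniform bands
  over [0, rate/2]. Each band's analysis filter is a brick-wall bandpass
  *centered* on the band center but widened to 2*max_mod_freq (at least
  one band spacing), so that a modulator up to max_mod_freq keeps both
  of its side bands inside the filter. Filters therefore overlap; band
  membership of a spectral line is still decided by the disjoint uniform
  partition (used e.g. to find "the band containing the pitch").
* The envelope is kept at full rate and analyzed with an FFT over the
  whole frame, so the modulation bins sit at multiples of 1/duration Hz
  and the DC (0 Hz) bin is retained — several morphological parameters
  are ratios against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ENVELOPE_MODES = ("hilbert", "coherent")


@dataclass
class ModSpec:
    """Complex modulation spectrum E indexed [acoustic band, modulation bin]."""

    E: np.ndarray                 # complex, (n_acoustic_bands, n_mod_bins)
    fa: np.ndarray                # Hz, acoustic band centers
    fm: np.ndarray                # Hz, modulation bin centers (fm[0] = 0)
    envelope_mode: str
    max_mod_freq: float
    acoustic_band_width: float    # Hz, width of the disjoint partition

    @property
    def n_acoustic_bands(self) -> int:
        return self.E.shape[0]

    @property
    def n_mod_bins(self) -> int:
        return self.E.shape[1]

    def modulus(self) -> np.ndarray:
        return np.abs(self.E)

    def acoustic_band_of(self, freq: float) -> int:
        """Index of the disjoint acoustic band containing ``freq``."""
        a = int(freq // self.acoustic_band_width)
        return min(max(a, 0), self.n_acoustic_bands - 1)

    def mod_band_of(self, freq: float) -> int:
        """Index of the modulation bin whose band contains ``freq``."""
        if len(self.fm) > 1:
            step = self.fm[1] - self.fm[0]
        else:
            step = max(self.max_mod_freq, 1.0)
        m = int(round(freq / step))
        return min(max(m, 0), self.n_mod_bins - 1)


@dataclass
class ReducedModSpec:
    """Modulus energy summed into a few contiguous modulation bands."""

    band_energy: np.ndarray       # (n_acoustic_bands, nb)
    band_edges: np.ndarray        # Hz, length nb+1
    fa: np.ndarray                # Hz, acoustic band centers

    @property
    def nb(self) -> int:
        return self.band_energy.shape[1]


def compute_modspec(frame: np.ndarray, rate: int,
                    n_acoustic_bands: int = 128,
                    max_mod_freq: float = 240.0,
                    envelope_mode: str = "hilbert") -> ModSpec:
    """Compute E(fa, fm) for one frame.

    Parameters
    ----------
    frame:
        Time-domain samples of a single analysis frame (any taper the
        caller wants applied must already be applied).
    max_mod_freq:
        Upper edge of the modulation axis, Hz (70-500 in practice).
    envelope_mode:
        ``"hilbert"`` detects the magnitude of the analytic subband
        signal; ``"coherent"`` demodulates by the band-center carrier
        and keeps the complex baseband signal.
    """
    if envelope_mode not in ENVELOPE_MODES:
        raise ValueError(f"unknown envelope_mode {envelope_mode!r}")
    x = np.asarray(frame, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("frame too short for envelope analysis")
    nyquist = rate / 2.0
    band_width = nyquist / n_acoustic_bands
    fa = (np.arange(n_acoustic_bands) + 0.5) * band_width

    mod_bin_hz = rate / n                      # = 1/duration
    n_mod_bins = int(np.floor(max_mod_freq / mod_bin_hz)) + 1
    n_mod_bins = min(n_mod_bins, n // 2 + 1)
    if mod_bin_hz > max_mod_freq / 4.0:
        import warnings
        warnings.warn(
            "frame is short relative to max_mod_freq: modulation "
            f"resolution {mod_bin_hz:.1f} Hz exceeds max_mod_freq/4")
    fm = np.arange(n_mod_bins) * mod_bin_hz

    X = np.fft.fft(x)
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    pos = freqs > 0
    half_bw = max(band_width, 2.0 * max_mod_freq) / 2.0

    # one-sided (analytic) masked spectra for all bands at once
    Z = np.zeros((n_acoustic_bands, n), dtype=complex)
    lo = fa - half_bw
    hi = fa + half_bw
    in_band = (freqs[None, :] >= lo[:, None]) & (freqs[None, :] < hi[:, None])
    in_band &= pos[None, :]
    Z[in_band] = np.broadcast_to(2.0 * X[None, :], Z.shape)[in_band]
    # DC of the frame belongs to the lowest filters (carrier-free content)
    dc_bands = (lo <= 0.0) & (hi > 0.0)
    Z[dc_bands, 0] = X[0]

    analytic = np.fft.ifft(Z, axis=1)
    if envelope_mode == "hilbert":
        env = np.abs(analytic)
    else:
        t = np.arange(n) / rate
        env = analytic * np.exp(-2j * np.pi * fa[:, None] * t[None, :])

    E = np.fft.fft(env, axis=1)[:, :n_mod_bins] / n
    return ModSpec(E=E, fa=fa, fm=fm, envelope_mode=envelope_mode,
                   max_mod_freq=float(max_mod_freq),
                   acoustic_band_width=band_width)


def unwrap_phase(ms: ModSpec, floor_rel: float = 1e-12) -> np.ndarray:
    """Unwrapped phase arg(E) over the (fa, fm) grid.

    Cells whose modulus falls below ``floor_rel * max|E|`` carry no usable
    phase and are zeroed before unwrapping. Unwrapping is the deterministic
    separable 2-D scheme: 1-D unwrap along the modulation axis of every
    acoustic band, then along the acoustic axis.
    """
    mag = np.abs(ms.E)
    phase = np.angle(ms.E)
    floor = floor_rel * (mag.max() if mag.size else 0.0)
    phase = np.where(mag <= floor, 0.0, phase)
    phase = np.unwrap(phase, axis=1)
    phase = np.unwrap(phase, axis=0)
    return phase


def reduce_mod_bands(ms: ModSpec, nb: int) -> ReducedModSpec:
    """Sum |E|^2 into ``nb`` contiguous equal-width modulation bands.

    The partition covers [0, max_mod_freq]; total energy is conserved
    (every modulation bin lands in exactly one band).
    """
    if nb < 1:
        raise ValueError("nb must be >= 1")
    if nb > ms.n_mod_bins:
        raise ValueError(
            f"cannot reduce {ms.n_mod_bins} modulation bins to {nb} bands")
    edges = np.linspace(0.0, ms.max_mod_freq, nb + 1)
    # assign each bin to the band whose half-open interval contains it;
    # the topmost edge is inclusive so no bin is dropped
    idx = np.clip(np.searchsorted(edges, ms.fm, side="right") - 1, 0, nb - 1)
    power = np.abs(ms.E) ** 2
    band_energy = np.zeros((ms.n_acoustic_bands, nb))
    for b in range(nb):
        sel = idx == b
        if sel.any():
            band_energy[:, b] = power[:, sel].sum(axis=1)
    return ReducedModSpec(band_energy=band_energy, band_edges=edges, fa=ms.fa)
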